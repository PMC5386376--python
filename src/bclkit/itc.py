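"""Single-site isothermal titration calorimetry: simulation and fitting.

The model is the standard single-site binding isotherm with the
perfusion-cell dilution convention used by MicroCal-style instruments.
After a cumulative injected volume ΔV into a cell of working volume V₀,
the total cell concentrations of macromolecule M and ligand X are

    [M]ₜ = M₀ · (1 − ΔV/2V₀) / (1 + ΔV/2V₀)
    [X]ₜ = X_s · (ΔV/V₀) / (1 + ΔV/2V₀)

and the bound concentration solves the quadratic mass-action balance

    [MX] = ½ [ (N[M]ₜ + [X]ₜ + 1/Kₐ) − √((N[M]ₜ + [X]ₜ + 1/Kₐ)² − 4N[M]ₜ[X]ₜ) ].

The cumulative heat is Q(i) = [MX]ᵢ · ΔH · V₀ and each injection's
measured heat includes the displaced-volume correction

    dQᵢ = Q(i) − Q(i−1) + (dVᵢ/V₀) · (Q(i) + Q(i−1))/2 + baseline.

Units: concentrations in M, volumes in μl, ΔH in cal/mol, heats in μcal
(Kd is reported in nM to match common practice).  The c-value
N·M₀/K_d governs curve shape: c ≈ 300 (tight nanomolar binding at a
20 μM cell concentration) gives a sharp sigmoid, c ≈ 5 a shallow one,
and fits in the low-c regime carry correspondingly wide uncertainties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

DEFAULT_CELL_VOLUME_UL = 204.4  # iTC200-class instrument working volume


@dataclass
class ITCExperiment:
    """Titration protocol, optionally carrying measured/simulated heats."""

    cell_volume: float = DEFAULT_CELL_VOLUME_UL  # μl
    cell_conc: float = 20e-6     # M macromolecule
    syringe_conc: float = 200e-6  # M ligand
    injection_volumes: list[float] = field(
        default_factory=lambda: [2.0] * 19
    )  # μl
    temperature: float = 25.0  # °C
    heats: list[float] | None = None  # μcal per injection

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")
        if self.heats is not None and len(self.heats) != len(self.injection_volumes):
            raise ValueError("heats and injection lists must have equal length")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class ITCModelParams:
    N: float          # stoichiometry
    Ka: float         # association constant, M⁻¹
    dH: float         # cal/mol
    baseline: float = 0.0  # μcal per injection

    def __post_init__(self) -> None:
        if self.Ka <= 0:
            raise ValueError("Ka must be positive")
        if self.N <= 0:
            raise ValueError("N must be positive")

    @property
    def kd_nM(self) -> float:
        return 1e9 / self.Ka


@dataclass
class FitResult:
    params: ITCModelParams
    kd_nM: float
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    no_binding: bool = False
    c_value: float | None = None


def _cumulative_heats(params: ITCModelParams, protocol: ITCExperiment) -> np.ndarray:
    """Q(i) in μcal after each injection (Q(0)=0 excluded)."""
    dV = np.asarray(protocol.injection_volumes, dtype=float)
    cum = np.cumsum(dV)
    v0 = protocol.cell_volume
    mt = protocol.cell_conc * (1 - cum / (2 * v0)) / (1 + cum / (2 * v0))
    xt = protocol.syringe_conc * (cum / v0) / (1 + cum / (2 * v0))
    s = params.N * mt + xt + 1.0 / params.Ka
    disc = np.maximum(s * s - 4.0 * params.N * mt * xt, 0.0)
    bound = 0.5 * (s - np.sqrt(disc))
    return bound * params.dH * v0  # M · cal/mol · μl ≡ μcal


def injection_heats(params: ITCModelParams, protocol: ITCExperiment) -> np.ndarray:
    """Noise-free per-injection heats (μcal), displaced-volume corrected."""
    q = _cumulative_heats(params, protocol)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dV = np.asarray(protocol.injection_volumes, dtype=float)
    correction = dV / protocol.cell_volume * (q + q_prev) / 2.0
    return q - q_prev + correction + params.baseline


def simulate_titration(
    params: ITCModelParams,
    protocol: ITCExperiment,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_fraction: float | None = None,
) -> ITCExperiment:
    """Simulate a titration; `noise_fraction` scales sd to the max |heat|."""
    clean = injection_heats(params, protocol)
    if noise_fraction is not None:
        noise_sd = noise_fraction * float(np.abs(clean - params.baseline).max())
    rng = np.random.default_rng(seed)
    heats = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return replace(protocol, heats=list(heats))


def c_value(params: ITCModelParams, protocol: ITCExperiment) -> float:
    """Wiseman c = N·[M]₀·Kₐ; rule of thumb: reliable fits need 1 ≲ c ≲ 1000."""
    return params.N * protocol.cell_conc * params.Ka


class NoBindingError(RuntimeError):
    pass


def _detect_no_binding(heats: np.ndarray) -> bool:
    """Flat-thermogram heuristic: peak excursion vs injection-to-injection noise."""
    baseline = float(np.median(heats))
    signal = float(np.abs(heats - baseline).max())
    diffs = np.diff(heats)
    noise = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / math.sqrt(2)
    return signal < max(5.0 * noise, 1e-6)


def _auto_init(exp: ITCExperiment, heats: np.ndarray) -> ITCModelParams:
    baseline0 = float(np.median(heats[-3:]))
    net = heats - baseline0
    total = float(net.sum())
    v0 = exp.cell_volume
    dh0 = total / (v0 * exp.cell_conc) if total != 0 else -1000.0
    # molar ratio at the half-heat point approximates N
    dV = np.asarray(exp.injection_volumes, dtype=float)
    cum = np.cumsum(dV)
    mt = exp.cell_conc * (1 - cum / (2 * v0)) / (1 + cum / (2 * v0))
    xt = exp.syringe_conc * (cum / v0) / (1 + cum / (2 * v0))
    ratio = xt / mt
    cum_heat = np.cumsum(net)
    half = total / 2.0
    n0 = 1.0
    if total != 0:
        idx = np.searchsorted(np.abs(cum_heat), abs(half))
        if 0 < idx < len(ratio):
            n0 = float(ratio[idx])
    n0 = float(np.clip(n0, 0.2, 5.0))
    return ITCModelParams(N=n0, Ka=1e7, dH=dh0, baseline=baseline0)


_LOGKA_GRID = (5.0, 6.0, 7.0, 8.0, 9.0)


def fit_single_site(
    exp: ITCExperiment,
    init: ITCModelParams | None = None,
    discard_first: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Nonlinear least-squares fit of (N, Ka, ΔH, baseline) to injection heats.

    Restarts from a small log-Ka grid with jittered starting points; the
    best converged solution wins.  A flat thermogram yields a no-binding
    verdict instead of a number.
    """
    if exp.heats is None:
        raise ValueError("experiment carries no heats to fit")
    if exp.n_injections < 8:
        raise ValueError("need at least 8 injections for a stable fit")
    heats = np.asarray(exp.heats, dtype=float)
    protocol = exp
    weights = np.ones_like(heats)
    if discard_first:
        weights[0] = 0.0
    if _detect_no_binding(heats if not discard_first else heats[1:]):
        params = ITCModelParams(N=1.0, Ka=1.0, dH=0.0,
                                baseline=float(np.median(heats)))
        return FitResult(params=params, kd_nM=float("nan"), stderr={},
                         residual_norm=float(np.std(heats)), converged=False,
                         no_binding=True)

    guess = init or _auto_init(exp, heats)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = ITCModelParams(N=x[0], Ka=10.0 ** x[1], dH=x[2], baseline=x[3])
        return (injection_heats(p, protocol) - heats) * weights

    bounds = ([0.05, 2.0, -1e6, -100.0], [10.0, 12.0, 1e6, 100.0])
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    base = np.array([guess.N, math.log10(guess.Ka), guess.dH, guess.baseline])
    starts.append(base)
    for logka in _LOGKA_GRID:
        starts.append(np.array([guess.N, logka, guess.dH, guess.baseline]))
    for _ in range(max(0, n_restarts - 1)):
        jitter = rng.normal(0, [0.2, 0.7, abs(guess.dH) * 0.2 + 1.0, 0.5])
        starts.append(base + jitter)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(
                residuals, x0, bounds=bounds, method="trf",
                x_scale=[1.0, 1.0, max(abs(guess.dH), 1e3), 1.0],
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        params = guess
        return FitResult(params=params, kd_nM=float("nan"), stderr={},
                         residual_norm=float("inf"), converged=False)

    x = best.x
    params = ITCModelParams(N=x[0], Ka=10.0 ** x[1], dH=x[2], baseline=x[3])
    n_used = int(weights.sum())
    dof = max(n_used - 4, 1)
    sigma2 = 2 * best.cost / dof
    stderr: dict[str, float] = {}
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * sigma2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        # log10Ka error → relative Ka/Kd error
        stderr = {
            "N": float(se[0]),
            "Ka_rel": float(se[1] * math.log(10)),
            "dH": float(se[2]),
            "baseline": float(se[3]),
            "kd_nM": float(params.kd_nM * se[1] * math.log(10)),
        }
    except np.linalg.LinAlgError:
        pass
    return FitResult(
        params=params,
        kd_nM=params.kd_nM,
        stderr=stderr,
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=True,
        c_value=c_value(params, protocol),
    )


def aggregate_replicates(fits: list[FitResult]) -> tuple[float, float]:
    """Mean ± sample SD (nM) of Kd over converged replicate fits."""
    kds = [f.kd_nM for f in fits if f.converged and not f.no_binding]
    if len(kds) < 2:
        raise ValueError(
            f"need ≥2 converged fits to aggregate, got {len(kds)}"
        )
    arr = np.asarray(kds)
    return float(arr.mean()), float(arr.std(ddof=1))
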