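"""BH3 motif detection in protein sequences.

The BH3 motif is a short amphipathic helical element of pro-apoptotic
Bcl-2 family proteins.  Its defining features are four hydrophobic
positions (h1–h4) with fixed spacing h1, h1+4, h1+7, h1+11, a strongly
conserved leucine at h2, and an invariant acidic residue (usually Asp)
two positions after h3.  A sliding template scores each placement:

    score = w(h1) + w_leu(h2) + w(h3) + w(h4) + w_acid(h1+9)

with default weights +2 for any of {A,I,L,M,F,V,W,Y} at h1/h3/h4, +3
for Leu at h2 (+1 for another hydrophobic), and +3/+2 for Asp/Glu at
the acid position.  The motif is short and weakly conserved, so the
scanner is a screening tool, not a proteome-scale classifier.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

HYDROPHOBIC = set("AILMFVWY")

#: template offsets relative to h1 (0-based)
H2_OFFSET, H3_OFFSET, ACID_OFFSET, H4_OFFSET = 4, 7, 9, 11
TEMPLATE_SPAN = H4_OFFSET + 1  # residues h1..h4 inclusive

DEFAULT_WEIGHTS = {
    "hydrophobic": 2.0,       # h1, h3, h4
    "leu_at_h2": 3.0,
    "other_hydrophobic_h2": 1.0,
    "asp_at_acid": 3.0,
    "glu_at_acid": 2.0,
}
DEFAULT_MIN_SCORE = 10.0


@dataclass(frozen=True)
class BH3Hit:
    sequence_id: str
    start: int  # 1-based position of h1
    end: int    # 1-based position of h4
    score: float
    h1: int
    h2: int
    h3: int
    h4: int
    acid: int

    def __post_init__(self) -> None:
        assert self.h2 == self.h1 + 4
        assert self.h3 == self.h1 + 7
        assert self.acid == self.h1 + 9
        assert self.h4 == self.h1 + 11

    @property
    def leu(self) -> int:
        """Position of the conserved-leucine slot (= h2)."""
        return self.h2


def _score_window(window: str, weights: dict[str, float]) -> float:
    score = 0.0
    for off in (0, H3_OFFSET, H4_OFFSET):
        if window[off] in HYDROPHOBIC:
            score += weights["hydrophobic"]
    h2 = window[H2_OFFSET]
    if h2 == "L":
        score += weights["leu_at_h2"]
    elif h2 in HYDROPHOBIC:
        score += weights["other_hydrophobic_h2"]
    acid = window[ACID_OFFSET]
    if acid == "D":
        score += weights["asp_at_acid"]
    elif acid == "E":
        score += weights["glu_at_acid"]
    return score


def scan_bh3(
    sequence: str,
    sequence_id: str = "seq",
    min_score: float = DEFAULT_MIN_SCORE,
    weights: dict[str, float] | None = None,
) -> list[BH3Hit]:
    """Scan a sequence for BH3-like placements, best-scoring first.

    Overlapping placements are resolved greedily: the highest-scoring
    hit is kept and any placement overlapping its h1..h4 span is
    discarded (ties broken by sequence position).
    """
    weights = weights or DEFAULT_WEIGHTS
    seq = sequence.upper()
    if len(seq) < TEMPLATE_SPAN:
        warnings.warn(
            f"{sequence_id}: sequence shorter than the {TEMPLATE_SPAN}-residue "
            "BH3 template", stacklevel=2,
        )
        return []
    candidates: list[BH3Hit] = []
    for i in range(len(seq) - TEMPLATE_SPAN + 1):
        window = seq[i : i + TEMPLATE_SPAN]
        score = _score_window(window, weights)
        if score >= min_score:
            h1 = i + 1
            candidates.append(
                BH3Hit(
                    sequence_id=sequence_id, start=h1, end=h1 + H4_OFFSET,
                    score=score, h1=h1, h2=h1 + H2_OFFSET, h3=h1 + H3_OFFSET,
                    h4=h1 + H4_OFFSET, acid=h1 + ACID_OFFSET,
                )
            )
    candidates.sort(key=lambda h: (-h.score, h.start))
    kept: list[BH3Hit] = []
    for hit in candidates:
        if all(hit.end < k.start or hit.start > k.end for k in kept):
            kept.append(hit)
    return kept


def peptide_window(sequence: str, hit: BH3Hit, length: int = 28) -> str:
    """Extract the peptide-synthesis window around a BH3 hit.

    The window is placed so that h1 falls at window position 10 — the
    offset of the first hot spot within the canonical 28-mer BH3
    peptide (motif residues 71–82 inside a 62–89 construct).  Windows
    that would run past the sequence ends are truncated with a warning.
    """
    start = hit.start - 9  # 1-based
    end = start + length - 1
    if start < 1 or end > len(sequence):
        warnings.warn(
            f"{hit.sequence_id}: {length}-mer window [{start}, {end}] exceeds "
            f"sequence bounds [1, {len(sequence)}]; truncated", stacklevel=2,
        )
        start = max(start, 1)
        end = min(end, len(sequence))
    return sequence[start - 1 : end]


def scan_fasta(
    path: str | Path,
    min_score: float = DEFAULT_MIN_SCORE,
    weights: dict[str, float] | None = None,
) -> list[BH3Hit]:
    """Scan every record of a FASTA file (lowercase input is upper-cased)."""
    hits: list[BH3Hit] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        hits.extend(scan_bh3(str(rec.seq).upper(), rec.id, min_score, weights))
    return hits
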