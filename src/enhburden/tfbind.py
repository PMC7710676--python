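"""Position-specific scoring-matrix comparison of wild-type vs mutant sequences.

Motifs come in as MEME-minimal letter-probability matrices and are
converted to log-odds against the motif's stated background with a small
pseudocount; arbitrary log-odds matrices can also be supplied directly.
Scanning covers every offset on both strands; ties break to the leftmost
offset with the forward strand preferred. ``N`` bases contribute the
background-expected score at their position.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, FormatError

__all__ = [
    "PSSM",
    "BindingDelta",
    "read_meme",
    "pssm_from_probabilities",
    "pssm_best_score",
    "binding_delta",
    "reverse_complement",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PSEUDOCOUNT = 1e-4


@dataclass
class PSSM:
    """Log-odds scoring matrix (L x 4, columns A,C,G,T) with its background."""

    motif_id: str
    weights: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.background = np.asarray(self.background, dtype=float)
        if self.weights.shape[1] != 4:
            raise FormatError("PSSM needs exactly 4 columns (A,C,G,T)")
        if self.weights.shape[0] < 1:
            raise FormatError("PSSM needs length >= 1")
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise FormatError("background must be 4 strictly positive frequencies")

    @property
    def length(self) -> int:
        return self.weights.shape[0]


@dataclass
class BindingDelta:
    motif_id: str
    best_score_wt: float
    best_score_mut: float
    delta: float  # positive = mutation weakens the best site
    best_offset_wt: int
    best_offset_mut: int
    strand: str  # strand of the best wild-type site


def pssm_from_probabilities(
    motif_id: str,
    probs: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> PSSM:
    """Convert a letter-probability matrix to log2-odds vs the background."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    adj = (probs + pseudocount) / (1.0 + 4.0 * pseudocount)
    weights = np.log2(adj / bg[None, :])
    return PSSM(motif_id=motif_id, weights=weights, background=bg)


def read_meme(path: str) -> list[PSSM]:
    """Parse a MEME-minimal motif file into log-odds PSSMs."""
    motifs: list[PSSM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freqs = {tokens[k]: float(tokens[k + 1]) for k in range(0, len(tokens), 2)}
            background = np.array([freqs.get(b, 0.25) for b in ALPHABET])
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without identifier")
            motif_id = parts[1]
            # seek the letter-probability matrix header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id} has no matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {motif_id} has no matrix")
            rows = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(tok) for tok in stripped.split()])
                i += 1
            if not rows:
                raise FormatError(f"{path}: motif {motif_id} matrix is empty")
            motifs.append(
                pssm_from_probabilities(motif_id, np.array(rows), background)
            )
            continue
        i += 1
    if not motifs:
        raise FormatError(f"{path}: no motifs found")
    return motifs


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_scores(seq: str, pssm: PSSM) -> np.ndarray:
    """Per-offset forward-strand scores; N contributes the background mean."""
    L = pssm.length
    n_off = len(seq) - L + 1
    expected = pssm.weights @ pssm.background  # per-position background score
    scores = np.empty(n_off)
    for off in range(n_off):
        total = 0.0
        for i in range(L):
            base = seq[off + i]
            idx = _BASE_INDEX.get(base)
            if idx is None:
                if base != "N":
                    raise DataError(f"unexpected base {base!r} in sequence")
                total += expected[i]
            else:
                total += pssm.weights[i, idx]
        scores[off] = total
    return scores


def pssm_best_score(seq: str, pssm: PSSM) -> tuple[float, int, str]:
    """Best (score, offset, strand) over all offsets and both strands.

    The minus-strand score at offset ``o`` is the forward score of the
    reverse complement aligned so that ``o`` indexes the original sequence.
    Ties: leftmost offset, forward strand first.
    """
    seq = seq.upper()
    if len(seq) < pssm.length:
        raise DataError(
            f"sequence length {len(seq)} shorter than motif length {pssm.length}"
        )
    fwd = _scan_scores(seq, pssm)
    rev = _scan_scores(reverse_complement(seq), pssm)[::-1]  # reindex to seq coords
    best = (-np.inf, -1, "+")
    for off in range(fwd.size):
        if fwd[off] > best[0]:
            best = (float(fwd[off]), off, "+")
        if rev[off] > best[0]:
            best = (float(rev[off]), off, "-")
    return best


def binding_delta(seq_wt: str, seq_mut: str, pssm: PSSM) -> BindingDelta:
    """Best-site score change between wild-type and mutant windows.

    Positive delta = the mutation weakens the best predicted site.
    Antisymmetric under swapping the two sequences.
    """
    score_wt, off_wt, strand_wt = pssm_best_score(seq_wt, pssm)
    score_mut, off_mut, _ = pssm_best_score(seq_mut, pssm)
    return BindingDelta(
        motif_id=pssm.motif_id,
        best_score_wt=score_wt,
        best_score_mut=score_mut,
        delta=score_wt - score_mut,
        best_offset_wt=off_wt,
        best_offset_mut=off_mut,
        strand=strand_wt,
    )
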