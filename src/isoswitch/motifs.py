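"""Promoter motif enrichment (Pscan-style) and gene-set over-representation.

A position frequency matrix is turned into a pseudocounted log-odds
matrix; each promoter gets the best log-odds hit over all offsets on both
strands, min-max normalized to [0, 1] by the matrix's attainable score
extremes.  Enrichment of a foreground gene set against a background is a
one-sided z-test on mean best-hit scores — the scheme popularized for
promoter CCAAT-box analysis.  Over-representation of a study set in GMT
gene sets is an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats as sps

from .errors import FormatError
from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "PWMatrix",
    "read_jaspar",
    "read_promoters",
    "best_hit_score",
    "score_promoters",
    "motif_ztest",
    "rank_motifs",
    "ora_hypergeom",
    "ora_table",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
#: reverse-complement index map; 4 encodes N/ambiguous
_RC = np.array([3, 2, 1, 0, 4])


@dataclass
class PWMatrix:
    """A position frequency matrix (rows A, C, G, T) with its log-odds form.

    ``pseudocount_frac`` is the fraction of each column total added to
    every cell; the background is uniform unless overridden.
    """

    name: str
    counts: np.ndarray
    matrix_id: str = ""
    pseudocount_frac: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(f"{self.name}: PFM must be 4 × width with width ≥ 4")
        if (self.counts < 0).any():
            raise ValueError(f"{self.name}: negative PFM counts")
        colsum = self.counts.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError(f"{self.name}: zero PFM column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0, keepdims=True)
        pc = self.pseudocount_frac * colsum
        freq = (self.counts + pc) / (colsum + 4 * pc)
        return np.log2(freq / self.background[:, None])

    @property
    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


def read_jaspar(path: str | Path) -> list[PWMatrix]:
    """Read a JASPAR-dialect PFM text file.

    Accepts both layouts: ``>ID NAME`` followed by four bare count rows,
    or rows of the form ``A  [ 1 2 3 ]``.
    """
    pwms: list[PWMatrix] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []
    order: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal header, rows, order
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"{path}:{lineno}: matrix {header[0]} has {len(rows)} rows, need 4")
        mat = np.array(rows, dtype=float)
        if order and order != list(_BASES):
            mat = mat[[order.index(b) for b in _BASES]]
        pwms.append(PWMatrix(name=header[1] or header[0], counts=mat, matrix_id=header[0]))
        header, rows, order = None, [], []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1].strip() if len(parts) > 1 else "")
                continue
            if header is None:
                raise FormatError(f"{path}:{lineno}: counts before any '>' header")
            base = None
            if line[0].upper() in _CODE and not line[0].isdigit():
                base = line[0].upper()
                line = line[1:]
            line = line.replace("[", " ").replace("]", " ")
            try:
                vals = [float(v) for v in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad count row") from exc
            if base:
                order.append(base)
            rows.append(vals)
        flush(lineno)
    if not pwms:
        raise FormatError(f"{path}: no matrices found")
    return pwms


def read_promoters(path: str | Path, expected_length: int | None = 500) -> dict[str, str]:
    """Promoter FASTA → {gene id: sequence}; sequences are upper-cased and
    must use the A/C/G/T/N alphabet.  A declared window length is enforced
    when ``expected_length`` is set."""
    promoters: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGTN"):
            raise FormatError(f"{path}: {rec.id}: non-ACGTN characters")
        if expected_length is not None and len(seq) != expected_length:
            raise FormatError(
                f"{path}: {rec.id}: length {len(seq)} != declared window {expected_length}")
        if rec.id in promoters:
            raise FormatError(f"{path}: duplicate promoter id {rec.id}")
        promoters[rec.id] = seq
    if not promoters:
        raise FormatError(f"{path}: empty FASTA")
    return promoters


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode().translate(
        bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))), dtype=np.uint8).astype(np.intp)


def _window_scores(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; windows touching an N score −inf."""
    w = lo.shape[1]
    lo_ext = np.vstack([lo, np.full((1, w), -np.inf)])
    wins = np.lib.stride_tricks.sliding_window_view(idx, w)
    return lo_ext[wins, np.arange(w)].sum(axis=1)


def best_hit_score(seq: str, pwm: PWMatrix) -> float:
    """Best normalized log-odds hit of ``pwm`` in ``seq`` over both strands.

    Scores are min-max normalized by the matrix's attainable extremes so
    1.0 is a perfect consensus match.  Returns NaN when no window is free
    of N (the caller excludes such promoters).
    """
    if len(seq) < pwm.width:
        raise ValueError(f"sequence shorter ({len(seq)}) than PWM width ({pwm.width})")
    idx = _encode(seq)
    lo = pwm.log_odds
    fwd = _window_scores(idx, lo)
    rev = _window_scores(_RC[idx][::-1], lo)
    best = max(fwd.max(), rev.max())
    if not np.isfinite(best):
        return float("nan")
    smin, smax = pwm.score_range
    if smax == smin:
        return 0.0
    return float((best - smin) / (smax - smin))


def score_promoters(promoters: Mapping[str, str], pwms: Sequence[PWMatrix]) -> pd.DataFrame:
    """Best-hit score of every PWM in every promoter (genes × matrices).

    Promoters with no N-free window get NaN (logged per matrix).
    """
    out = {}
    for pwm in pwms:
        col = {g: best_hit_score(s, pwm) for g, s in promoters.items()}
        n_bad = sum(np.isnan(v) for v in col.values())
        if n_bad:
            logger.warning("score_promoters: %s: %d promoters with no valid window",
                           pwm.name, n_bad)
        out[pwm.name] = col
    return pd.DataFrame(out)


def motif_ztest(
    fg_genes: Sequence[str],
    scores: pd.Series | Mapping[str, float],
    bg_genes: Sequence[str] | None = None,
) -> tuple[float, float]:
    """One-sided z-test for elevated motif scores in a foreground set.

    ``scores`` holds per-gene normalized best-hit scores for one matrix;
    the background defaults to all scored genes.

        z = (mean_fg − mean_bg) / (sd_bg / sqrt(n_fg))

    Returns (z, upper-tail p).  NaN scores are excluded; a zero-variance
    background gives (nan, nan).
    """
    scores = pd.Series(scores, dtype=float)
    fg = scores.reindex(list(fg_genes)).dropna()
    if len(set(fg_genes)) < 5:
        raise ValueError("foreground set needs at least 5 genes")
    bg = scores.dropna() if bg_genes is None else scores.reindex(list(bg_genes)).dropna()
    if len(bg) < 2:
        raise ValueError("background too small")
    # population sd: the background is treated as the reference population,
    # which also makes the test exactly invariant to duplicating it
    sd = float(bg.std(ddof=0))
    if sd == 0:
        return float("nan"), float("nan")
    z = (fg.mean() - bg.mean()) / (sd / np.sqrt(len(fg)))
    return float(z), float(sps.norm.sf(z))


def rank_motifs(
    fg_genes: Sequence[str],
    promoters: Mapping[str, str],
    pwms: Sequence[PWMatrix],
    bg_genes: Sequence[str] | None = None,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank a PWM library by foreground enrichment (ascending p, ties by z).

    Precomputed ``scores`` (from :func:`score_promoters`) may be supplied
    to amortize scanning over repeated foreground sets.
    """
    if scores is None:
        scores = score_promoters(promoters, pwms)
    rows = []
    for pwm in pwms:
        z, p = motif_ztest(fg_genes, scores[pwm.name], bg_genes)
        rows.append({"matrix": pwm.name, "matrix_id": pwm.matrix_id, "z": z, "pvalue": p})
    out = pd.DataFrame(rows).sort_values(["pvalue", "z"], ascending=[True, False],
                                         kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("matrix")


def ora_hypergeom(study_set: Sequence[str], gene_set: Sequence[str],
                  universe: Sequence[str]) -> float:
    """Upper-tail hypergeometric p for the study/gene-set overlap."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    study = set(study_set)
    gset = set(gene_set) & uni
    if not study <= uni:
        raise ValueError("study set must be contained in the universe")
    k = len(study & gset)
    return float(sps.hypergeom.sf(k - 1, len(uni), len(gset), len(study)))


def ora_table(study_set: Sequence[str], gene_sets: Mapping[str, Sequence[str]],
              universe: Sequence[str]) -> pd.DataFrame:
    """Hypergeometric ORA across a GMT collection, BH-corrected."""
    rows = []
    study = set(study_set)
    for name, members in gene_sets.items():
        overlap = len(study & set(members) & set(universe))
        rows.append({"gene_set": name, "overlap": overlap, "set_size": len(set(members)),
                     "pvalue": ora_hypergeom(study_set, members, universe)})
    out = pd.DataFrame(rows).set_index("gene_set")
    out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    return out.sort_values("pvalue", kind="stable")


# ---------------------------------------------------------------------------
# Synthetic fixtures: a CCAAT-box matrix and a decoy library.  These are
# synthetic stand-ins generated for testing and demonstration; they are not
# database matrices.

def synthetic_ccaat_pwm(strength: int = 85, total: int = 100) -> PWMatrix:
    """A synthetic NF-Y-like matrix whose consensus is the CCAAT box."""
    rest = (total - strength) / 3.0
    cols = []
    for base in "CCAAT":
        col = np.full(4, rest)
        col[_CODE[base]] = strength
        cols.append(col)
    return PWMatrix(name="NFY_CCAAT", counts=np.array(cols).T, matrix_id="SYN0001")


def synthetic_pwm_library(
    n_decoys: int = 19,
    rng: np.random.Generator | int | None = 0,
    width_range: tuple[int, int] = (6, 12),
    total: int = 100,
) -> list[PWMatrix]:
    """The CCAAT matrix plus ``n_decoys`` random synthetic matrices.

    Decoys have a random consensus with comparable per-column information
    content, so library ranking is a fair contest.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pwms = [synthetic_ccaat_pwm(total=total)]
    for i in range(n_decoys):
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        cols = []
        for _ in range(w):
            col = np.full(4, (total - 85) / 3.0)
            col[rng.integers(4)] = 85.0
            cols.append(col)
        pwms.append(PWMatrix(name=f"DECOY{i:02d}", counts=np.array(cols).T,
                             matrix_id=f"SYN1{i:03d}"))
    return pwms


def random_promoters(
    n: int,
    length: int = 500,
    rng: np.random.Generator | int | None = 0,
    prefix: str = "GENE",
) -> dict[str, str]:
    """Random uniform-base promoter windows (synthetic fixture)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seqs = rng.integers(0, 4, size=(n, length))
    lut = np.array(list("ACGT"))
    return {f"{prefix}{i:04d}": "".join(lut[s]) for i, s in enumerate(seqs)}


def plant_motif(promoters: Mapping[str, str], motif: str, position: int) -> dict[str, str]:
    """Copy of ``promoters`` with ``motif`` written at ``position`` (0-based)."""
    out = {}
    for g, s in promoters.items():
        if position + len(motif) > len(s):
            raise ValueError("motif does not fit at the requested position")
        out[g] = s[:position] + motif + s[position + len(motif):]
    return out
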