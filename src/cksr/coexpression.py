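"""Co-expression scoring of convergent kinase groups across cell lines.

A convergent relationship can only operate in a cell that expresses at least
two of the converging kinases.  Given an expression matrix over cell lines
(transcriptomic, stored as log2(TPM + 1); or MS proteomic, stored as relative
abundances), each gene is binarized to expressed / not expressed and every
convergent kinase group is scored as the percentage of cell lines in which
>= 2 of its members are expressed.

Thresholding follows the data modality: TPM-scale data use an absolute cutoff
(TPM >= 5, 10 or 20; inclusive, applied in stored log2 space as
``value >= log2(threshold + 1)``), whereas relative MS abundances use a
per-gene median with strict inequality — only a relative cutoff is defensible
for bridge-normalized intensities, and ties or missing values count as not
expressed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CCLE_HEADER_RE = re.compile(r"^\s*(\S+)\s*\(.*\)\s*$")


class MatrixFormatError(ValueError):
    """Expression matrix malformed (non-numeric cell, bad headers...)."""


@dataclass
class ExpressionMatrix:
    """Cell lines x genes matrix with a declared measurement scale.

    ``data`` has cell lines as the index and HGNC-cropped gene symbols as
    columns; missing measurements are NaN.  ``scale`` is ``"log2_tpm_plus1"``
    or ``"ms_relative"``.
    """

    data: pd.DataFrame
    scale: str
    n_duplicate_symbols_dropped: int = 0

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class BinaryExpressionMatrix:
    """Binarized expression (1 expressed / 0 not), with threshold provenance."""

    data: pd.DataFrame
    threshold_spec: dict = field(default_factory=dict)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)


def crop_symbol(header: str) -> str:
    """Crop a CCLE-style ``"SYMBOL (ID)"`` column header to the bare symbol."""
    m = _CCLE_HEADER_RE.match(header)
    return (m.group(1) if m else header).strip().upper()


def load_expression_matrix(
    path: str | Path, dialect: str = "ccle_csv", scale: str = "log2_tpm_plus1"
) -> ExpressionMatrix:
    """Load a cell-lines-by-genes expression matrix.

    ``ccle_csv`` is comma-separated with ``"SYMBOL (ID)"`` gene headers which
    are cropped to the bare HGNC symbol; ``plain_tsv`` is tab-separated with
    bare symbols.  When cropping produces duplicate symbols, the column with
    the highest mean expression is kept and the rest dropped with a warning.
    A non-numeric cell is a format error reporting its coordinates.
    """
    path = Path(path)
    sep = "," if dialect == "ccle_csv" else "\t"
    if dialect not in ("ccle_csv", "plain_tsv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.index[coerced.isna() & raw[col].notna()]
            cell_line = bad[0] if len(bad) else "?"
            raise MatrixFormatError(
                f"non-numeric value at (cell line {cell_line!r}, gene {col!r}) in {path}"
            )
    raw.columns = [crop_symbol(str(c)) for c in raw.columns]
    raw.index = [str(i).strip() for i in raw.index]

    n_dropped = 0
    if raw.columns.duplicated().any():
        keep: dict[str, int] = {}
        means = raw.mean(axis=0).to_numpy()
        for pos, sym in enumerate(raw.columns):
            if sym not in keep or means[pos] > means[keep[sym]]:
                keep[sym] = pos
        n_dropped = raw.shape[1] - len(keep)
        logger.warning("dropped %d duplicate gene symbol column(s) after cropping", n_dropped)
        raw = raw.iloc[:, sorted(keep.values())]
    if scale == "log2_tpm_plus1" and (raw.to_numpy() < 0).any():
        raise MatrixFormatError("log2(TPM+1) matrix contains negative values")
    return ExpressionMatrix(data=raw, scale=scale, n_duplicate_symbols_dropped=n_dropped)


def binarize_expression(
    m: ExpressionMatrix, mode: str = "tpm", tpm_threshold: float = 10.0
) -> BinaryExpressionMatrix:
    """Convert an expression matrix to binary expressed / not expressed calls.

    ``mode="tpm"`` (requires log2(TPM+1) scale): expressed iff TPM >= threshold,
    evaluated as stored value >= log2(threshold + 1).  ``mode="median"`` (for
    relative MS data): expressed iff the value is strictly greater than that
    gene's across-cell-line median; requires >= 2 non-missing values per gene.
    Missing values are never expressed.
    """
    if mode == "tpm":
        if m.scale != "log2_tpm_plus1":
            raise ValueError(f"tpm mode requires log2_tpm_plus1 scale, got {m.scale!r}")
        if tpm_threshold <= 0:
            raise ValueError("tpm_threshold must be positive")
        cutoff = math.log2(tpm_threshold + 1.0)
        binary = (m.data >= cutoff).astype("int8")
        spec = {"mode": "tpm", "tpm_threshold": tpm_threshold, "stored_cutoff": cutoff}
    elif mode == "median":
        if m.scale == "log2_tpm_plus1":
            raise ValueError("median mode is for relative (MS) scales; use mode='tpm'")
        n_obs = m.data.notna().sum(axis=0)
        thin = n_obs[n_obs < 2]
        if len(thin):
            raise ValueError(
                f"median mode needs >= 2 non-missing values per gene; "
                f"offending gene(s): {list(thin.index)[:5]}"
            )
        medians = m.data.median(axis=0, skipna=True)
        binary = m.data.gt(medians, axis=1).astype("int8")
        spec = {"mode": "median", "per": "gene", "strict": True}
    else:
        raise ValueError(f"unknown binarization mode: {mode!r}")
    binary = binary.where(m.data.notna(), 0).astype("int8")
    return BinaryExpressionMatrix(data=binary, threshold_spec=spec)


@dataclass
class CoexpressionScore:
    """Co-expression of one convergent kinase group across all cell lines.

    ``score`` is the percentage of cell lines in which >= 2 group members are
    expressed.  Groups with fewer than two members present in the matrix are
    flagged unscored (``scored=False``) rather than raising.
    """

    target: str
    kinase_group: tuple[str, ...]
    n_in_matrix: int
    n_lines_coexpressed: int
    n_cell_lines: int
    score: float
    scored: bool = True


def coexpression_score(
    target: str, group: Iterable[str], b: BinaryExpressionMatrix
) -> CoexpressionScore:
    """Score one kinase group: % of cell lines with >= 2 members expressed.

    Kinases absent from the matrix are treated as never expressed (the score
    can only be underestimated); ``n_in_matrix`` records how many were found.
    """
    group = tuple(sorted({g.upper() for g in group}))
    if len(group) < 2:
        raise ValueError(f"group for {target!r} has fewer than 2 kinases")
    present = [g for g in group if g in b.data.columns]
    n_lines = len(b.data.index)
    if len(present) < 2:
        return CoexpressionScore(
            target=target, kinase_group=group, n_in_matrix=len(present),
            n_lines_coexpressed=0, n_cell_lines=n_lines, score=float("nan"), scored=False,
        )
    n_co = int((b.data[present].sum(axis=1) >= 2).sum())
    return CoexpressionScore(
        target=target, kinase_group=group, n_in_matrix=len(present),
        n_lines_coexpressed=n_co, n_cell_lines=n_lines,
        score=100.0 * n_co / n_lines if n_lines else 0.0,
    )


def score_groups(
    groups: dict[str, set[str]], b: BinaryExpressionMatrix
) -> list[CoexpressionScore]:
    """Score every convergent kinase group (target -> kinase set) in turn."""
    return [coexpression_score(t, ks, b) for t, ks in sorted(groups.items())]


@dataclass
class ScoreSummary:
    median: float
    mean: float
    fraction_below: float  # percent of scored groups under the rarity cutoff
    rarity_cutoff: float
    n_scored: int
    n_unscored: int
    empty: bool = False


def score_distribution_summary(
    scores: Sequence[CoexpressionScore], rarity_cutoff: float = 2.5
) -> ScoreSummary:
    """Summarize a set of group scores (median, mean, rare-co-expression rate).

    ``rarity_cutoff`` is the score (in percent of cell lines) under which a
    group counts as rarely co-expressed; 2.5% by default.  Unscored groups are
    counted separately and excluded from the statistics.
    """
    vals = np.array([s.score for s in scores if s.scored], dtype=float)
    n_unscored = sum(1 for s in scores if not s.scored)
    if vals.size == 0:
        return ScoreSummary(
            median=float("nan"), mean=float("nan"), fraction_below=float("nan"),
            rarity_cutoff=rarity_cutoff, n_scored=0, n_unscored=n_unscored, empty=True,
        )
    return ScoreSummary(
        median=float(np.median(vals)),
        mean=float(np.mean(vals)),
        fraction_below=100.0 * float(np.mean(vals < rarity_cutoff)),
        rarity_cutoff=rarity_cutoff,
        n_scored=int(vals.size),
        n_unscored=n_unscored,
    )


def scores_table(scores: Sequence[CoexpressionScore]) -> pd.DataFrame:
    """Scores as a table, one row per target group."""
    rows = [
        {
            "target": s.target,
            "kinases": "; ".join(s.kinase_group),
            "n_in_matrix": s.n_in_matrix,
            "n_lines_coexpressed": s.n_lines_coexpressed,
            "n_cell_lines": s.n_cell_lines,
            "score": s.score,
            "scored": s.scored,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "target", "kinases", "n_in_matrix", "n_lines_coexpressed",
            "n_cell_lines", "score", "scored",
        ],
    )


def analytic_coexpression_probability(probs: Sequence[float]) -> float:
    """Closed-form P(>= 2 of n independent Bernoulli(p_i) kinases expressed).

    1 - P(none) - P(exactly one); the expected co-expression score of a group
    under independent expression is 100x this value.
    """
    probs = list(probs)
    if any(not (0.0 <= p <= 1.0) for p in probs):
        raise ValueError("probabilities must lie in [0, 1]")
    p_none = float(np.prod([1.0 - p for p in probs]))
    p_one = 0.0
    for i, p in enumerate(probs):
        rest = float(np.prod([1.0 - q for j, q in enumerate(probs) if j != i]))
        p_one += p * rest
    return 1.0 - p_none - p_one
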