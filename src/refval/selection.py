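"""Stability filter cascades for reference- and validation-gene selection.

Two selectors over a genes × conditions TPM matrix, both working on the
log₂TPM scale:

* **Reference path** — stable, highly expressed genes suitable as RT-qPCR
  endogenous controls.  Five filters, applied in order:

  1. expression: every TPM strictly above ``min_tpm`` (default 0);
  2. stability: sample SD of log₂TPM strictly below ``sd_max`` (default 1);
  3. no outlier library: max |log₂TPM − mean| strictly below ``dev_max``
     (default 2);
  4. expression level: mean log₂TPM strictly above ``mean_min`` (default 5,
     i.e. TPM ≳ 32);
  5. relative stability: CV = SD/mean of log₂TPM strictly below ``cv_max``
     (default 0.2).

  Survivors are ranked by CV ascending (most stable first).

* **Validation path** — variable yet highly expressed genes, good targets
  for confirming RNA-seq differential expression by RT-qPCR.  Three filters:
  expression (as above); SD of log₂TPM strictly above ``sd_min`` (default
  1); mean log₂TPM strictly above ``mean_min``.  Survivors are ranked by SD
  descending (most variable first).

All cutoffs are strict inequalities: a gene sitting exactly on a boundary
fails.  With the default cutoffs the two outputs are disjoint (SD < 1
vs. SD > 1).  A gene is counted against the first filter it fails, which is
what the per-filter survivor counts in :class:`CascadeReport` record.

The estimators follow scikit-learn conventions (``fit`` on a conditions ×
genes array, ``get_support``/``transform``, ``get_params``); gene
identifiers are taken from DataFrame column names when available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .matrix import ExpressionMatrix

__all__ = [
    "FilterThresholds",
    "GeneStatistics",
    "CandidateRecord",
    "CandidateTable",
    "CascadeReport",
    "AnalysisResult",
    "compute_gene_statistics",
    "passes_expression",
    "build_candidate_table",
    "ReferenceGeneSelector",
    "ValidationGeneSelector",
    "select_reference_candidates",
    "select_validation_candidates",
    "query_candidate_rank",
    "analyze",
]

REFERENCE_FILTERS = (
    "min_expression",
    "sd_ceiling",
    "deviation_ceiling",
    "mean_floor",
    "cv_ceiling",
)
VALIDATION_FILTERS = ("min_expression", "sd_floor", "mean_floor")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FilterThresholds:
    """The six cutoffs parameterizing the two cascades (all strict).

    ``min_tpm`` applies on the raw TPM scale; the rest apply to log₂TPM
    statistics.  ``sd_max``/``dev_max``/``mean_min``/``cv_max`` drive the
    reference path, ``sd_min`` the validation path.
    """

    min_tpm: float = 0.0
    sd_max: float = 1.0
    dev_max: float = 2.0
    mean_min: float = 5.0
    cv_max: float = 0.2
    sd_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("min_tpm", "sd_max", "dev_max", "mean_min", "cv_max", "sd_min"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"threshold {name} must be finite, got {v!r}")
        if self.sd_max <= 0 or self.dev_max <= 0 or self.cv_max <= 0:
            raise ValueError("sd_max, dev_max and cv_max must be positive")


@dataclass(frozen=True)
class GeneStatistics:
    """Per-gene log₂TPM summary used by every filter past the first."""

    gene_id: str
    log2_values: np.ndarray
    log2_mean: float
    log2_sd: float
    cv: float
    max_abs_dev: float


@dataclass(frozen=True)
class CandidateRecord:
    """One row of a ranked candidate table.

    ``cv`` is ``None`` on the validation path, where the CV filter plays no
    role and the published tables print "Not calculated".
    """

    rank: int
    gene_id: str
    sd: float
    log2_mean: float
    cv: Optional[float]


@dataclass
class CandidateTable:
    """Ordered candidate list: CV-ascending (reference) or SD-descending
    (validation), ranks 1-based and consecutive."""

    path_kind: str  # "reference" | "validation"
    records: list[CandidateRecord]

    def __post_init__(self) -> None:
        if self.path_kind not in ("reference", "validation"):
            raise ValueError(f"unknown path_kind {self.path_kind!r}")
        for i, rec in enumerate(self.records, start=1):
            if rec.rank != i:
                raise ValueError(f"rank {rec.rank} at position {i}: ranks must be consecutive from 1")
        keys = [r.cv for r in self.records] if self.path_kind == "reference" else [-r.sd for r in self.records]
        if any(k is None for k in keys):
            raise ValueError("reference records must carry a CV")
        if any(b < a for a, b in zip(keys, keys[1:])):
            raise ValueError(f"records are not sorted for a {self.path_kind} table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns Rank, ID, SD, TPM_Avrg, CV."""
        return pd.DataFrame(
            {
                "Rank": [r.rank for r in self.records],
                "ID": [r.gene_id for r in self.records],
                "SD": [r.sd for r in self.records],
                "TPM_Avrg": [r.log2_mean for r in self.records],
                "CV": [r.cv for r in self.records],
            }
        )


@dataclass
class CascadeReport:
    """Survivor counts after each filter of one path (first-failure
    semantics: a gene is charged to the first filter it fails)."""

    path_kind: str
    input_count: int
    survivors: list[tuple[str, int]]

    def __post_init__(self) -> None:
        counts = [self.input_count] + [c for _, c in self.survivors]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("survivor counts must be non-increasing along the cascade")

    @property
    def final_count(self) -> int:
        return self.survivors[-1][1] if self.survivors else self.input_count


@dataclass
class AnalysisResult:
    """Both candidate tables and both cascade reports from one run."""

    reference: CandidateTable
    reference_report: CascadeReport
    validation: CandidateTable
    validation_report: CascadeReport


# ---------------------------------------------------------------------------
# per-gene statistics


def compute_gene_statistics(values, ddof: int = 1, gene_id: str = "") -> GeneStatistics:
    """log₂TPM statistics of one gene across conditions.

    Parameters
    ----------
    values : array-like of float
        Strictly positive TPM values, one per condition, length ≥ 2.
    ddof : int
        0 for the population SD (divisor n), 1 for the sample SD
        (divisor n−1, the default).

    Notes
    -----
    CV is the ratio SD/mean of the *log₂* values; it is only meaningful for
    a positive mean (mean log₂TPM > 0, i.e. average TPM above 1).  For a
    zero mean the ratio is returned as ``nan``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise ValueError("all TPM values must be positive and finite")
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    log2 = np.log2(arr)
    mean = float(log2.mean())
    sd = float(log2.std(ddof=ddof))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = float(np.divide(sd, mean)) if mean != 0.0 else float("nan")
    dev = float(np.abs(log2 - mean).max())
    return GeneStatistics(gene_id, log2, mean, sd, cv, dev)


def passes_expression(values, min_tpm: float = 0.0) -> bool:
    """True iff every value is strictly above ``min_tpm`` (the expression
    filter; a single zero library disqualifies the gene at the default)."""
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("TPM values must be finite")
    return bool((arr > min_tpm).all())


# ---------------------------------------------------------------------------
# ranking


def build_candidate_table(
    path_kind: str,
    entries: Iterable[tuple[str, float, float, Optional[float]]],
) -> CandidateTable:
    """Rank (gene_id, sd, log2_mean, cv) entries into a candidate table.

    Reference tables sort by CV ascending, validation tables by SD
    descending; ties are broken by gene identifier (lexicographic) so output
    order is fully deterministic.
    """
    entries = list(entries)
    if path_kind == "reference":
        entries.sort(key=lambda e: (e[3], e[0]))
    elif path_kind == "validation":
        entries.sort(key=lambda e: (-e[1], e[0]))
    else:
        raise ValueError(f"unknown path_kind {path_kind!r}")
    cv_kept = path_kind == "reference"
    records = [
        CandidateRecord(rank=i, gene_id=g, sd=float(sd), log2_mean=float(m),
                        cv=(float(cv) if cv_kept else None))
        for i, (g, sd, m, cv) in enumerate(entries, start=1)
    ]
    return CandidateTable(path_kind, records)


def query_candidate_rank(table: CandidateTable, gene_id: str) -> Optional[CandidateRecord]:
    """Look up a gene in a ranked table; ``None`` means not listed (a
    distinguishable signal, not an error)."""
    for rec in table.records:
        if rec.gene_id == gene_id:
            return rec
    return None


# ---------------------------------------------------------------------------
# vectorised cascade internals


def _log2_statistics(V: np.ndarray, m1: np.ndarray, ddof: int):
    """Stats per gene for eligible rows; ineligible rows are NaN."""
    n = V.shape[0]
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    dev = np.full(n, np.nan)
    cv = np.full(n, np.nan)
    if m1.any():
        L = np.log2(V[m1])
        mu = L.mean(axis=1)
        sig = L.std(axis=1, ddof=ddof)
        mean[m1] = mu
        sd[m1] = sig
        dev[m1] = np.abs(L - mu[:, None]).max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv[m1] = np.where(mu != 0.0, sig / np.where(mu != 0.0, mu, 1.0), np.nan)
    return mean, sd, dev, cv


class _BaseCascadeSelector(SelectorMixin, BaseEstimator):
    """Shared fit machinery; subclasses define the post-expression masks."""

    path_kind: str = ""
    filter_labels: tuple[str, ...] = ()

    def fit(self, X, y=None):
        if hasattr(X, "shape") and X.shape[1] == 0:
            # gene-less input: legal, yields empty tables and zeroed report
            self.n_features_in_ = 0
            X = np.empty((int(X.shape[0]), 0), dtype=np.float64)
        else:
            X = validate_data(self, X, dtype=np.float64, ensure_min_samples=2)
        if X.size and ((X < 0).any() or not np.isfinite(X).all()):
            raise ValueError("TPM values must be finite and non-negative")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")
        self.thresholds_ = self._thresholds()

        if hasattr(self, "feature_names_in_"):
            ids = np.asarray(self.feature_names_in_, dtype=object)
        else:
            ids = np.asarray([f"g{i}" for i in range(X.shape[1])], dtype=object)

        V = np.ascontiguousarray(X.T)  # genes x conditions
        m1 = np.all(V > self.min_tpm, axis=1)
        mean, sd, dev, cv = _log2_statistics(V, m1, self.ddof)
        masks = [m1] + self._cascade_masks(m1, mean, sd, dev, cv)

        self.statistics_ = pd.DataFrame(
            {"log2_mean": mean, "log2_sd": sd, "cv": cv, "max_abs_dev": dev},
            index=pd.Index(ids, name="ID"),
        )
        final = masks[-1]
        self.support_ = final
        keep_cv = self.path_kind == "reference"
        entries = [
            (str(ids[i]), float(sd[i]), float(mean[i]), float(cv[i]) if keep_cv else None)
            for i in np.flatnonzero(final)
        ]
        self.candidate_table_ = build_candidate_table(self.path_kind, entries)
        self.candidates_ = self.candidate_table_.to_frame()
        self.cascade_report_ = CascadeReport(
            self.path_kind,
            input_count=int(V.shape[0]),
            survivors=[(lab, int(m.sum())) for lab, m in zip(self.filter_labels, masks)],
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_

    # subclass hooks -------------------------------------------------------

    def _thresholds(self) -> FilterThresholds:  # pragma: no cover - abstract
        raise NotImplementedError

    def _cascade_masks(self, m1, mean, sd, dev, cv):  # pragma: no cover
        raise NotImplementedError


class ReferenceGeneSelector(_BaseCascadeSelector):
    """Select stable, highly expressed genes (RT-qPCR reference candidates).

    scikit-learn-style selector: ``fit`` expects ``X`` with conditions as
    rows and genes as columns (pass a DataFrame to keep gene identifiers).

    Parameters
    ----------
    min_tpm : float, default 0
        Expression floor on the raw TPM scale (strict: a gene with a single
        library at exactly ``min_tpm`` is dropped).
    sd_max : float, default 1
        Ceiling on the sample SD of log₂TPM.
    dev_max : float, default 2
        Ceiling on the largest |log₂TPM − mean log₂TPM| over libraries.
    mean_min : float, default 5
        Floor on mean log₂TPM (5 ≙ average TPM of 32).
    cv_max : float, default 0.2
        Ceiling on CV = SD/mean of log₂TPM.
    ddof : {1, 0}, default 1
        SD divisor convention: 1 → n−1 (sample SD), 0 → n.

    Attributes
    ----------
    support_ : bool array of shape (n_genes,)
        Mask of genes passing every filter.
    candidate_table_ : CandidateTable
        Survivors ranked by CV ascending, ties broken by identifier.
    candidates_ : pandas.DataFrame
        The same ranking as a Rank/ID/SD/TPM_Avrg/CV table.
    cascade_report_ : CascadeReport
        Survivor count after each of the five filters.
    statistics_ : pandas.DataFrame
        Per-gene log2_mean, log2_sd, cv, max_abs_dev (NaN where the
        expression filter already failed).

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"stable": [64, 64, 64], "noisy": [1, 1024, 4]},
    ...                  index=["c1", "c2", "c3"], dtype=float)
    >>> ReferenceGeneSelector().fit(X).candidate_table_.gene_ids
    ['stable']
    """

    path_kind = "reference"
    filter_labels = REFERENCE_FILTERS

    def __init__(self, min_tpm: float = 0.0, sd_max: float = 1.0, dev_max: float = 2.0,
                 mean_min: float = 5.0, cv_max: float = 0.2, ddof: int = 1):
        self.min_tpm = min_tpm
        self.sd_max = sd_max
        self.dev_max = dev_max
        self.mean_min = mean_min
        self.cv_max = cv_max
        self.ddof = ddof

    def _thresholds(self) -> FilterThresholds:
        return FilterThresholds(min_tpm=self.min_tpm, sd_max=self.sd_max,
                                dev_max=self.dev_max, mean_min=self.mean_min,
                                cv_max=self.cv_max)

    def _cascade_masks(self, m1, mean, sd, dev, cv):
        with np.errstate(invalid="ignore"):
            m2 = m1 & (sd < self.sd_max)
            m3 = m2 & (dev < self.dev_max)
            m4 = m3 & (mean > self.mean_min)
            # CV compares like with like only for a positive mean; with the
            # default mean_min of 5 this is automatic, but a user-set
            # mean_min <= 0 can let non-positive means through to this stage.
            nonpos = m4 & ~(mean > 0)
            if nonpos.any():
                warnings.warn(
                    f"{int(nonpos.sum())} gene(s) reached the CV filter with a "
                    "non-positive mean log2(TPM); CV is ill-defined there and "
                    "those genes were excluded",
                    UserWarning,
                    stacklevel=2,
                )
            m5 = m4 & (mean > 0) & (cv < self.cv_max)
        return [m2, m3, m4, m5]


class ValidationGeneSelector(_BaseCascadeSelector):
    """Select variable, highly expressed genes (RT-qPCR validation
    candidates): expression floor, SD of log₂TPM strictly above ``sd_min``,
    mean log₂TPM strictly above ``mean_min``; ranked by SD descending.

    See :class:`ReferenceGeneSelector` for the estimator conventions; the
    fitted attributes are the same, except candidate records carry no CV.
    """

    path_kind = "validation"
    filter_labels = VALIDATION_FILTERS

    def __init__(self, min_tpm: float = 0.0, sd_min: float = 1.0,
                 mean_min: float = 5.0, ddof: int = 1):
        self.min_tpm = min_tpm
        self.sd_min = sd_min
        self.mean_min = mean_min
        self.ddof = ddof

    def _thresholds(self) -> FilterThresholds:
        return FilterThresholds(min_tpm=self.min_tpm, mean_min=self.mean_min,
                                sd_min=self.sd_min)

    def _cascade_masks(self, m1, mean, sd, dev, cv):
        with np.errstate(invalid="ignore"):
            m2 = m1 & (sd > self.sd_min)
            m3 = m2 & (mean > self.mean_min)
        return [m2, m3]


# ---------------------------------------------------------------------------
# functional wrappers over the estimators


def _as_samples(matrix: ExpressionMatrix) -> pd.DataFrame:
    if not isinstance(matrix, ExpressionMatrix):
        raise TypeError("expected an ExpressionMatrix")
    return matrix.to_samples_frame()


def select_reference_candidates(
    matrix: ExpressionMatrix,
    thresholds: FilterThresholds | None = None,
    ddof: int = 1,
) -> tuple[CandidateTable, CascadeReport]:
    """Run the five-filter reference cascade on an expression matrix."""
    thr = thresholds or FilterThresholds()
    sel = ReferenceGeneSelector(
        min_tpm=thr.min_tpm, sd_max=thr.sd_max, dev_max=thr.dev_max,
        mean_min=thr.mean_min, cv_max=thr.cv_max, ddof=ddof,
    ).fit(_as_samples(matrix))
    return sel.candidate_table_, sel.cascade_report_


def select_validation_candidates(
    matrix: ExpressionMatrix,
    thresholds: FilterThresholds | None = None,
    ddof: int = 1,
) -> tuple[CandidateTable, CascadeReport]:
    """Run the three-filter validation cascade on an expression matrix."""
    thr = thresholds or FilterThresholds()
    sel = ValidationGeneSelector(
        min_tpm=thr.min_tpm, sd_min=thr.sd_min, mean_min=thr.mean_min, ddof=ddof,
    ).fit(_as_samples(matrix))
    return sel.candidate_table_, sel.cascade_report_


def analyze(
    matrix: ExpressionMatrix,
    thresholds: FilterThresholds | None = None,
    ddof: int = 1,
) -> AnalysisResult:
    """Run both cascades in one call (the single "Analysis" step)."""
    ref_tab, ref_rep = select_reference_candidates(matrix, thresholds, ddof)
    val_tab, val_rep = select_validation_candidates(matrix, thresholds, ddof)
    return AnalysisResult(ref_tab, ref_rep, val_tab, val_rep)
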