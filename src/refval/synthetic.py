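"""Synthetic quantification benchmark with known ground-truth gene groups.

Builds a controlled TPM matrix (default 50,000 genes × 6 libraries, values
in [0.01, 1000], no zeros) whose genes fall into three constraint-defined
groups relative to the reference-path filter cutoffs:

* **group1** (default 49,500 genes) — fails at least the CV filter: noisy
  genes that must never reach the reference list;
* **group2** (default 400 genes) — passes every reference filter: the
  ground-truth reference set;
* **group3** (default 100 genes) — stable genes with low expression: passes
  every filter *except* the expression-level floor (mean log₂TPM > 5).
  Variant 2 additionally constrains group3 to CV < 0.05, the regime where
  rank-only stability methods promote unamplifiable genes.

Group membership is enforced by rejection sampling: candidate genes are
drawn (per-gene base log₂ level uniform in a group-specific window,
per-library Gaussian jitter on the log₂ scale, clipped to the value range)
and kept only if :func:`classify_gene` confirms the intended label, so the
emitted quotas are exact by construction.  Identical seed ⇒ identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .selection import FilterThresholds

__all__ = [
    "SyntheticSpec",
    "LabeledMatrix",
    "LabelReport",
    "GenerationError",
    "classify_gene",
    "generate_dataset",
    "verify_labels",
    "write_dataset",
    "read_labels",
]

GROUP_LABELS = ("group1", "group2", "group3")


class GenerationError(RuntimeError):
    """A group quota could not be filled within the attempt budget."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    ``group_quotas`` is (group1, group2, group3); ``variant`` 2 adds the
    CV < ``group3_cv_max`` constraint to group3.  ``attempt_factor`` bounds
    rejection sampling at ``attempt_factor × quota`` candidate draws per
    group before failing loudly.
    """

    n_libraries: int = 6
    value_min: float = 0.01
    value_max: float = 1000.0
    group_quotas: tuple[int, int, int] = (49_500, 400, 100)
    variant: int = 1
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    seed: int = 0
    ddof: int = 1
    group3_cv_max: float = 0.05
    attempt_factor: int = 1000

    def __post_init__(self) -> None:
        if self.n_libraries < 2:
            raise ValueError("need at least 2 libraries")
        if not (0 < self.value_min < self.value_max):
            raise ValueError("require 0 < value_min < value_max")
        if any(q < 0 for q in self.group_quotas) or len(self.group_quotas) != 3:
            raise ValueError("group_quotas must be three non-negative counts")
        if self.variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return int(sum(self.group_quotas))


@dataclass
class LabeledMatrix:
    """A generated matrix plus its per-gene ground-truth group labels."""

    matrix: ExpressionMatrix
    labels: pd.Series  # index: gene id, values in GROUP_LABELS

    def __post_init__(self) -> None:
        if list(self.labels.index) != self.matrix.gene_ids:
            raise ValueError("labels must be indexed by the matrix's gene ids, in order")
        bad = set(self.labels.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")

    def gene_ids_of(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])

    def quota_counts(self) -> tuple[int, int, int]:
        return tuple(int((self.labels == g).sum()) for g in GROUP_LABELS)


@dataclass
class LabelReport:
    """Outcome of re-classifying every gene against its stored label."""

    ok: bool
    group_totals: dict[str, int]
    group_confirmed: dict[str, int]
    mismatches: list[tuple[str, str, str]]  # (gene id, expected, observed)


# ---------------------------------------------------------------------------
# classification


def _batch_stats(values: np.ndarray, thr: FilterThresholds, ddof: int):
    """Per-row log₂ stats + criterion masks for a (n, k) positive matrix."""
    L = np.log2(values)
    mean = L.mean(axis=1)
    sd = L.std(axis=1, ddof=ddof)
    dev = np.abs(L - mean[:, None]).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, sd / np.where(mean != 0.0, mean, 1.0), np.inf)
    c1 = np.all(values > thr.min_tpm, axis=1)
    c2 = sd < thr.sd_max
    c3 = dev < thr.dev_max
    c4 = mean > thr.mean_min
    c5 = (mean > 0) & (cv < thr.cv_max)
    return (c1, c2, c3, c4, c5), cv


def _classify_batch(values: np.ndarray, thr: FilterThresholds, ddof: int):
    """Group codes per row: 1/2/3, 0 = unclassifiable.  Returns (codes, cv)."""
    (c1, c2, c3, c4, c5), cv = _batch_stats(values, thr, ddof)
    codes = np.zeros(values.shape[0], dtype=np.int8)
    codes[c1 & ~c5] = 1
    codes[c1 & c2 & c3 & c5 & ~c4] = 3
    codes[c1 & c2 & c3 & c4 & c5] = 2
    return codes, cv


def classify_gene(values, thresholds: FilterThresholds | None = None, ddof: int = 1) -> str:
    """Classify one TPM vector against the reference-path criteria.

    Returns ``"group2"`` when all five criteria hold, ``"group3"`` when only
    the expression-level floor fails, ``"group1"`` when the CV criterion
    fails (the expression criterion holding), and ``"unclassifiable"``
    otherwise (e.g. the SD ceiling fails while the CV passes).
    """
    thr = thresholds or FilterThresholds()
    arr = np.asarray(values, dtype=float).reshape(1, -1)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise ValueError("synthetic classification requires positive finite values")
    codes, _ = _classify_batch(arr, thr, ddof)
    return {0: "unclassifiable", 1: "group1", 2: "group2", 3: "group3"}[int(codes[0])]


# ---------------------------------------------------------------------------
# generation


def _group_proposals(spec: SyntheticSpec):
    """Base-level windows and jitter-scale ranges per group (log₂ scale).

    Windows sit inside the value range with margin so that clipping is rare;
    jitter scales are broad enough to spread CVs over each group's regime.
    """
    thr = spec.thresholds
    lo = math.log2(spec.value_min)
    hi = math.log2(spec.value_max)
    high_lo = max(thr.mean_min + 0.3, lo)
    if high_lo >= hi - 0.2:
        raise GenerationError(
            "expression-level floor leaves no headroom inside the value range"
        )
    low_hi = min(thr.mean_min - 0.3, hi)
    if low_hi <= 0.5 and spec.group_quotas[2] > 0:
        raise GenerationError(
            "no window for stable low-expression genes: mean_floor too low"
        )
    g3_scale = (0.004, 0.04) if spec.variant == 2 else (0.01, 0.15)
    return {
        1: ((lo, hi), (1.2, 4.0)),
        2: ((high_lo, hi - 0.2), (0.02, 0.8)),
        3: ((0.5, low_hi), g3_scale),
    }


def generate_dataset(spec: SyntheticSpec) -> LabeledMatrix:
    """Generate the benchmark matrix and its ground-truth labels.

    Rejection sampling per group until each quota is met; rows from all
    groups are then shuffled together (seeded) and named gene1…geneN so gene
    order carries no label information.

    Raises
    ------
    GenerationError
        If a quota is not met within ``attempt_factor × quota`` draws.
    """
    rng = np.random.default_rng(spec.seed)
    proposals = _group_proposals(spec) if spec.n_genes else {}
    k = spec.n_libraries
    thr = spec.thresholds

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for code, quota in zip((1, 2, 3), spec.group_quotas):
        if quota == 0:
            continue
        (b_lo, b_hi), (s_lo, s_hi) = proposals[code]
        rows: list[np.ndarray] = []
        accepted = 0
        drawn = 0
        budget = spec.attempt_factor * quota
        while accepted < quota:
            batch = int(min(max(2 * (quota - accepted), 1024), 200_000))
            base = rng.uniform(b_lo, b_hi, batch)
            scale = rng.uniform(s_lo, s_hi, batch)
            log2v = base[:, None] + rng.normal(0.0, 1.0, (batch, k)) * scale[:, None]
            vals = np.clip(np.exp2(log2v), spec.value_min, spec.value_max)
            codes, cv = _classify_batch(vals, thr, spec.ddof)
            ok = codes == code
            if spec.variant == 2 and code == 3:
                ok &= cv < spec.group3_cv_max
            take = vals[ok][: quota - accepted]
            if len(take):
                rows.append(take)
                accepted += len(take)
            drawn += batch
            if accepted < quota and drawn >= budget:
                raise GenerationError(
                    f"group{code}: only {accepted}/{quota} genes accepted after "
                    f"{drawn} draws (budget {budget}); thresholds may make the "
                    "group infeasible"
                )
        blocks.append(np.vstack(rows))
        labels.extend([f"group{code}"] * quota)

    n = spec.n_genes
    if n == 0:
        values = np.empty((0, k))
        label_arr = np.array([], dtype=object)
    else:
        values = np.vstack(blocks)
        label_arr = np.array(labels, dtype=object)
        perm = rng.permutation(n)
        values = values[perm]
        label_arr = label_arr[perm]

    gene_ids = [f"gene{i}" for i in range(1, n + 1)]
    condition_labels = [f"lib{j}" for j in range(1, k + 1)]
    matrix = ExpressionMatrix.from_values(gene_ids, condition_labels, values)
    return LabeledMatrix(matrix, pd.Series(label_arr, index=pd.Index(gene_ids), name="group"))


def verify_labels(
    labeled: LabeledMatrix,
    thresholds: FilterThresholds | None = None,
    ddof: int = 1,
) -> LabelReport:
    """Independently re-classify every gene and confirm its stored label."""
    thr = thresholds or FilterThresholds()
    values = labeled.matrix.values
    if len(values):
        codes, _ = _classify_batch(values, thr, ddof)
        observed = np.array(
            ["unclassifiable", "group1", "group2", "group3"], dtype=object
        )[codes]
    else:
        observed = np.array([], dtype=object)
    expected = labeled.labels.to_numpy(dtype=object)
    mism = [
        (g, e, o)
        for g, e, o in zip(labeled.matrix.gene_ids, expected, observed)
        if e != o
    ]
    totals = {g: int((expected == g).sum()) for g in GROUP_LABELS}
    confirmed = {
        g: int(((expected == g) & (observed == expected)).sum()) for g in GROUP_LABELS
    }
    return LabelReport(ok=not mism, group_totals=totals,
                       group_confirmed=confirmed, mismatches=mism)


# ---------------------------------------------------------------------------
# persistence


def write_dataset(
    labeled: LabeledMatrix,
    matrix_path: str | Path,
    labels_path: str | Path,
    dialect: str = "csv",
) -> None:
    """Write the matrix (table-input layout) and a two-column label file
    (gene id, group)."""
    from .io import write_expression_table

    write_expression_table(labeled.matrix, matrix_path, dialect=dialect)
    labeled.labels.rename_axis("gene").to_csv(labels_path, sep="\t", header=["group"])


def read_labels(path: str | Path) -> pd.Series:
    """Read a label file written by :func:`write_dataset`."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return frame["group"].rename_axis("gene")
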