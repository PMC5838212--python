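"""Normalization and enrichment calling for EV miRNA count matrices.

Hybridization-counter assays (NanoString nCounter style) report one raw count
per probe per sample, alongside positive-control probes (a spike-in ladder of
synthetic RNAs, used to remove lane-to-lane technical scale) and
negative-control probes (no-target probes that measure non-specific
background).  The analysis chain implemented here is:

1. :func:`spikein_normalize` — rescale each sample so positive-control totals
   agree (geometric-mean scaling).
2. :func:`quantile_normalize` — force every sample's endogenous-count
   distribution onto the cross-sample average distribution.
3. :func:`fold_change` / :func:`call_enriched` — per-miRNA fold change of each
   stimulus condition against the constitutive-release baseline; cargo is
   called "enriched" at fold change >= 1.5 (inclusive).
4. :func:`detect_mirnas` — a miRNA counts as detected when it rises above the
   negative-control background (mean + k*SD) in at least one sample.
5. :func:`cluster_heatmap` — hierarchical clustering of log2 per-condition
   median counts for heatmap display.
6. :func:`ddct_relative_expression` — 2^-ddCt relative quantification for
   qRT-PCR validation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import gmean

PROBE_CLASSES = ("endogenous", "positive", "negative")

__all__ = [
    "MiRNACountMatrix",
    "EnrichmentResult",
    "CtTable",
    "ClusterResult",
    "spikein_normalize",
    "quantile_normalize",
    "fold_change",
    "call_enriched",
    "detect_mirnas",
    "cluster_heatmap",
    "ddct_relative_expression",
]


@dataclass
class MiRNACountMatrix:
    """Probe x sample count matrix with control-probe flags and conditions.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample.  Nonnegative
        integers when raw, nonnegative reals once normalized.
    probe_class
        Series mapping probe id -> one of ``endogenous`` / ``positive`` /
        ``negative``.
    conditions
        Series mapping sample id -> condition label (e.g. ``ADEV-CR``).
    state
        ``raw`` | ``spikein_normalized`` | ``quantile_normalized``.
    """

    values: pd.DataFrame
    probe_class: pd.Series
    conditions: pd.Series
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.probe_class = pd.Series(self.probe_class, dtype=object)
        self.conditions = pd.Series(self.conditions, dtype=object)
        self.validate()

    def validate(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = self.values.index.difference(self.probe_class.index)
        if len(missing):
            raise ValueError(f"probes without a class annotation: {list(missing)[:5]}")
        bad = set(self.probe_class.loc[self.values.index]) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        unlabeled = self.values.columns.difference(self.conditions.index)
        if len(unlabeled):
            raise ValueError(f"samples without a condition label: {list(unlabeled)[:5]}")
        if self.state not in ("raw", "spikein_normalized", "quantile_normalized"):
            raise ValueError(f"unknown state {self.state!r}")

    def probes_of(self, probe_class: str) -> pd.Index:
        cls = self.probe_class.loc[self.values.index]
        return self.values.index[cls == probe_class]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.values.loc[self.probes_of("endogenous")]

    def samples_in(self, condition: str) -> list[str]:
        cond = self.conditions.loc[self.values.columns]
        return list(self.values.columns[cond == condition])

    def condition_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.conditions[s], None)
        return list(seen)


@dataclass
class EnrichmentResult:
    """miRNAs enriched in one stimulus condition versus the baseline."""

    condition: str
    entries: list[tuple[str, float]]  # (miRNA id, fold change), FC >= threshold
    threshold: float = 1.5

    def mirnas(self) -> set[str]:
        return {m for m, _ in self.entries}


@dataclass
class CtTable:
    """qRT-PCR cycle-threshold table for ddCt relative quantification.

    ``data`` has columns ``sample``, ``group`` (``calibrator``/``treated``),
    ``target`` and ``ct``; ``housekeeping`` names the reference target that
    must be measured in every sample.
    """

    data: pd.DataFrame
    housekeeping: str

    def __post_init__(self) -> None:
        required = {"sample", "group", "target", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        ct = self.data["ct"].to_numpy(float)
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValueError("Ct values must be finite and > 0")
        for sample, sub in self.data.groupby("sample"):
            if self.housekeeping not in set(sub["target"]):
                raise ValueError(
                    f"housekeeping target {self.housekeeping!r} missing for sample {sample!r}"
                )


@dataclass
class ClusterResult:
    """Hierarchical-clustering output backing a heatmap."""

    matrix: pd.DataFrame  # log2 values, rows/cols in leaf order
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normalization


def spikein_normalize(m: MiRNACountMatrix) -> MiRNACountMatrix:
    """Scale each sample so positive-control spike-in totals agree.

    Each sample is multiplied by (geometric mean over samples of the
    positive-control sum) / (this sample's positive-control sum), so that
    after scaling every sample has the same spike-in total.
    """
    if m.state != "raw":
        raise ValueError(f"spike-in normalization expects raw counts, got {m.state!r}")
    pos = m.probes_of("positive")
    if len(pos) == 0:
        raise ValueError("no positive-control probes present")
    pos_sums = m.values.loc[pos].sum(axis=0)
    zero = pos_sums.index[pos_sums == 0]
    if len(zero):
        raise ValueError(f"zero positive-control counts in sample(s): {list(zero)}")
    factors = gmean(pos_sums.to_numpy()) / pos_sums
    out = m.values.mul(factors, axis=1)
    return replace(m, values=out, state="spikein_normalized")


def _quantile_normalize_values(x: np.ndarray) -> np.ndarray:
    """Classic quantile normalization; ties get the mean of the tied ranks'
    reference values (deterministic, order-independent)."""
    n, s = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.take_along_axis(x, order, axis=0).mean(axis=1)
    out = np.empty((n, s), dtype=float)
    for j in range(s):
        idx = order[:, j]
        vals = x[idx, j]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and vals[k + 1] == vals[i]:
                k += 1
            out[idx[i : k + 1], j] = ref[i : k + 1].mean()
            i = k + 1
    return out


def quantile_normalize(m: MiRNACountMatrix) -> MiRNACountMatrix:
    """Force every sample's endogenous counts onto the common rank-mean
    distribution.  Control probes are technical and pass through unchanged."""
    if m.state != "spikein_normalized":
        raise ValueError(
            f"quantile normalization expects spike-in-normalized counts, got {m.state!r}"
        )
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    endo = m.probes_of("endogenous")
    out = m.values.copy()
    out.loc[endo] = _quantile_normalize_values(m.values.loc[endo].to_numpy(float))
    return replace(m, values=out, state="quantile_normalized")


# ---------------------------------------------------------------------------
# enrichment


def fold_change(
    m: MiRNACountMatrix,
    baseline: str,
    *,
    pseudocount: float = 0.5,
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-miRNA fold change of every non-baseline condition vs the baseline.

    FC = (per-condition mean over replicate samples) / (baseline mean),
    endogenous probes only.  When the baseline mean is exactly zero the
    pseudocount is added to both numerator and denominator.

    Returns a tidy frame with columns ``mirna``, ``condition``,
    ``fold_change``.
    """
    if m.state != "quantile_normalized":
        raise ValueError(f"fold change expects quantile-normalized counts, got {m.state!r}")
    if baseline not in m.condition_labels():
        raise ValueError(f"unknown baseline condition {baseline!r}")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    endo = m.endogenous
    agg = np.mean if stat == "mean" else np.median

    def cond_stat(cond: str) -> pd.Series:
        return endo[m.samples_in(cond)].apply(agg, axis=1)

    base = cond_stat(baseline)
    rows = []
    for cond in m.condition_labels():
        if cond == baseline:
            continue
        num = cond_stat(cond)
        for mirna in endo.index:
            b, v = base[mirna], num[mirna]
            if b == 0:
                fc = (v + pseudocount) / (b + pseudocount)
            else:
                fc = v / b
            rows.append({"mirna": mirna, "condition": cond, "fold_change": fc})
    return pd.DataFrame(rows, columns=["mirna", "condition", "fold_change"])


def call_enriched(fc: pd.DataFrame, threshold: float = 1.5) -> list[EnrichmentResult]:
    """Call enriched cargo per condition: fold change >= threshold (inclusive,
    "1.5-fold or greater")."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    results = []
    for cond, sub in fc.groupby("condition", sort=False):
        hits = sub[sub["fold_change"] >= threshold]
        entries = list(zip(hits["mirna"], hits["fold_change"]))
        results.append(EnrichmentResult(condition=cond, entries=entries, threshold=threshold))
    return results


def detect_mirnas(
    m: MiRNACountMatrix,
    *,
    multiplier: float = 2.0,
    floor: float | None = None,
) -> set[str]:
    """miRNAs detected above the negative-control background.

    A miRNA is detected when its count exceeds (negative-control mean +
    ``multiplier`` * negative-control SD), computed within the same sample, in
    at least one sample.  With no negative controls an explicit ``floor``
    threshold must be supplied.
    """
    neg = m.probes_of("negative")
    endo = m.endogenous
    if len(neg) == 0:
        if floor is None:
            raise ValueError("no negative-control probes and no explicit floor configured")
        thresholds = pd.Series(floor, index=m.values.columns)
    else:
        negvals = m.values.loc[neg]
        thresholds = negvals.mean(axis=0) + multiplier * negvals.std(axis=0, ddof=1)
        if floor is not None:
            thresholds = thresholds.clip(lower=floor)
    above = endo.gt(thresholds, axis=1)
    return set(endo.index[above.any(axis=1)])


# ---------------------------------------------------------------------------
# clustering


def cluster_heatmap(
    m: MiRNACountMatrix,
    subset: Iterable[str] | None = None,
    *,
    metric: str = "euclidean",
    method: str = "complete",
    pseudocount: float = 1.0,
) -> ClusterResult:
    """Hierarchically cluster log2 per-condition median counts.

    Rows are miRNAs (optionally restricted to ``subset``), columns are
    conditions; each cell is log2(median normalized count across the
    condition's replicate samples + pseudocount).  Rows and columns are
    clustered agglomeratively (Euclidean distance, complete linkage by
    default) and returned in leaf order together with the merge trees.
    """
    endo = m.endogenous
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("subset must be nonempty")
        missing = set(subset) - set(endo.index)
        if missing:
            raise ValueError(f"unknown miRNAs in subset: {sorted(missing)[:5]}")
        endo = endo.loc[subset]
    conds = m.condition_labels()
    med = pd.DataFrame(
        {c: endo[m.samples_in(c)].median(axis=1) for c in conds}, index=endo.index
    )
    if ((med + pseudocount) <= 0).any().any():
        raise ValueError("nonpositive values after pseudocount; increase pseudocount")
    logm = np.log2(med + pseudocount)

    def _tree(x: np.ndarray):
        if x.shape[0] < 2:
            return None, list(range(x.shape[0]))
        z = hierarchy.linkage(x, method=method, metric=metric)
        return z, list(hierarchy.leaves_list(z))

    row_z, row_ord = _tree(logm.to_numpy())
    col_z, col_ord = _tree(logm.to_numpy().T)
    ordered = logm.iloc[row_ord, col_ord]
    return ClusterResult(
        matrix=ordered,
        row_linkage=row_z,
        col_linkage=col_z,
        row_order=list(ordered.index),
        col_order=list(ordered.columns),
        params={"metric": metric, "method": method, "pseudocount": pseudocount},
    )


# ---------------------------------------------------------------------------
# qRT-PCR


def ddct_relative_expression(t: CtTable, target: str) -> float:
    """Relative expression 2^-ddCt of ``target`` in treated vs calibrator.

    dCt = Ct(target) - Ct(housekeeping) per sample, averaged within group;
    ddCt = dCt(treated) - dCt(calibrator).
    """
    d = t.data
    dcts: dict[str, float] = {}
    for group in ("calibrator", "treated"):
        sub = d[d["group"] == group]
        if sub.empty:
            raise ValueError(f"missing group {group!r} in Ct table")
        tgt = sub[sub["target"] == target]
        if tgt.empty:
            raise ValueError(f"target {target!r} missing from group {group!r}")
        hk = sub[sub["target"] == t.housekeeping].set_index("sample")["ct"]
        per_sample = tgt.set_index("sample")["ct"] - hk.reindex(tgt["sample"]).to_numpy()
        dcts[group] = float(per_sample.mean())
    ddct = dcts["treated"] - dcts["calibrator"]
    return float(2.0 ** (-ddct))
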