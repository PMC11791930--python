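"""Group-comparison statistics: effect sizes, multiplicity control and
volcano classification.

For every feature (m/z column) of two cell groups the package computes
Cohen's D — the standardized mean difference (group1 − group2).  Because
the feature matrix is z-standardized upstream, the pooled standard
deviation is 1 by construction and D reduces to the difference of group
means (``assume_unit_sd=True``, the default path on standardized data);
the pooled-sd denominator is available for unstandardized input.

Per-feature p-values come from Welch's two-sample t-test (robust to the
unequal variances typical of activation data; Mann-Whitney is available)
and are Benjamini-Hochberg adjusted across features.  A feature is
classified ``up`` when D exceeds the effect-size threshold (default
+0.2) with adjusted p below the significance threshold, ``down``
symmetrically, else ``ns``.

For tissue images, where neighboring pixels are statistically dependent,
the volcano is computed on repeated random pixel subsamples (default
1000 pixels per condition, 10 repeats) and the per-feature effect sizes
and p-values are averaged across repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._errors import WorkflowError

log = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NS = "ns"

#: sign convention: D = mean(group1) - mean(group2); pass treatment as
#: group1 so activation markers come out positive.
SIGN_CONVENTION = "group1 - group2 (treatment minus vehicle)"


def cohens_d(group1, group2, assume_unit_sd: bool = False) -> float:
    """Cohen's D between two groups of values.

    With ``assume_unit_sd`` (the appropriate path on z-standardized
    data) the denominator is 1 and D is simply the difference of means;
    otherwise the pooled sample standard deviation is used.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise WorkflowError("each group needs at least 2 values")
    diff = g1.mean() - g2.mean()
    if assume_unit_sd:
        return float(diff)
    n1, n2 = len(g1), len(g2)
    pooled = np.sqrt(
        ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone-enforced, capped at 1, input order preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise WorkflowError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise WorkflowError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class VolcanoTable:
    """Per-feature effect size, raw/adjusted p and significance class."""

    frame: pd.DataFrame
    d_threshold: float
    p_threshold: float
    sign_convention: str = SIGN_CONVENTION

    COLUMNS = ("mz", "cohens_d", "p_raw", "p_adj", "class")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise WorkflowError(f"volcano table missing columns {missing}")

    def counts(self) -> dict:
        return self.frame["class"].value_counts().to_dict()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# Cohen's D sign convention: {self.sign_convention}\n")
            fh.write(f"# thresholds: |D| > {self.d_threshold}, "
                     f"adjusted p < {self.p_threshold}\n")
            self.frame.to_csv(fh, index=False)


def _classify(d: np.ndarray, p_adj: np.ndarray, d_threshold: float,
              p_threshold: float) -> np.ndarray:
    cls = np.full(len(d), NS, dtype=object)
    cls[(d > d_threshold) & (p_adj < p_threshold)] = UP
    cls[(d < -d_threshold) & (p_adj < p_threshold)] = DOWN
    return cls


def volcano(group1: np.ndarray, group2: np.ndarray, feature_mz,
            d_threshold: float = 0.2, p_threshold: float = 0.05,
            assume_unit_sd: bool = True, test: str = "welch") -> VolcanoTable:
    """Feature-wise two-group comparison.

    ``group1``/``group2`` are (cells × features) matrices sharing the
    feature axis; pass the treatment group first so the sign convention
    holds.  Features constant in both groups have no defined test: they
    get p = 1, class ``ns`` and a ``degenerate`` flag.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[1] != g2.shape[1]:
        raise WorkflowError("groups must share the feature axis")
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise WorkflowError("each group needs at least 2 cells")
    feature_mz = np.asarray(feature_mz, dtype=float)

    d = np.array([
        cohens_d(g1[:, j], g2[:, j], assume_unit_sd=assume_unit_sd)
        for j in range(g1.shape[1])
    ])
    degenerate = (g1.std(axis=0) == 0) & (g2.std(axis=0) == 0)
    if test == "welch":
        import warnings as _warnings

        with _warnings.catch_warnings():
            # constant columns trigger a precision warning; they are
            # flagged degenerate and forced to p=1 below
            _warnings.simplefilter("ignore", RuntimeWarning)
            p_raw = sps.ttest_ind(g1, g2, axis=0, equal_var=False).pvalue
    elif test == "mannwhitney":
        p_raw = np.array([
            sps.mannwhitneyu(g1[:, j], g2[:, j], alternative="two-sided").pvalue
            if not degenerate[j] else np.nan
            for j in range(g1.shape[1])
        ])
    else:
        raise WorkflowError(f"unknown test {test!r}")
    p_raw = np.where(degenerate | np.isnan(p_raw), 1.0, p_raw)
    if degenerate.any():
        log.warning("volcano: %d feature(s) constant in both groups (test undefined)",
                    int(degenerate.sum()))
    p_adj = bh_adjust(p_raw)
    frame = pd.DataFrame({
        "mz": feature_mz,
        "cohens_d": d,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "class": _classify(d, p_adj, d_threshold, p_threshold),
        "degenerate": degenerate,
    })
    return VolcanoTable(frame, d_threshold, p_threshold)


def subsample_pixels(pixels_by_condition: dict, feature_mz,
                     n_per_condition: int = 1000, repeats: int = 10,
                     rng=None, d_threshold: float = 0.2,
                     p_threshold: float = 0.05,
                     assume_unit_sd: bool = True) -> VolcanoTable:
    """Volcano on repeated random pixel subsamples, averaged.

    Adjacent tissue pixels are statistically dependent; subsampling
    breaks that dependence so p-values are not artificially inflated.
    Exactly two conditions are compared (first = group1).  Conditions
    with fewer than ``n_per_condition`` pixels contribute all their
    pixels (with a warning).  Raw and adjusted p-values are averaged
    separately across repeats; classification uses the averaged values.
    """
    if len(pixels_by_condition) != 2:
        raise WorkflowError("subsample_pixels compares exactly two conditions")
    rng = np.random.default_rng(rng)
    (name1, pix1), (name2, pix2) = pixels_by_condition.items()
    pix1 = np.atleast_2d(np.asarray(pix1, dtype=float))
    pix2 = np.atleast_2d(np.asarray(pix2, dtype=float))
    for name, pix in ((name1, pix1), (name2, pix2)):
        if len(pix) < n_per_condition:
            log.warning("condition %r has %d < %d pixels; using all of them",
                        name, len(pix), n_per_condition)

    tables = []
    for _ in range(repeats):
        sub = []
        for pix in (pix1, pix2):
            if len(pix) > n_per_condition:
                idx = rng.choice(len(pix), size=n_per_condition, replace=False)
                sub.append(pix[idx])
            else:
                sub.append(pix)
        tables.append(volcano(sub[0], sub[1], feature_mz, d_threshold,
                              p_threshold, assume_unit_sd=assume_unit_sd))
    d = np.mean([t.frame["cohens_d"].to_numpy() for t in tables], axis=0)
    p_raw = np.mean([t.frame["p_raw"].to_numpy() for t in tables], axis=0)
    p_adj = np.mean([t.frame["p_adj"].to_numpy() for t in tables], axis=0)
    frame = pd.DataFrame({
        "mz": np.asarray(feature_mz, dtype=float),
        "cohens_d": d,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "class": _classify(d, p_adj, d_threshold, p_threshold),
        "n_repeats": repeats,
    })
    return VolcanoTable(frame, d_threshold, p_threshold)


def marker_concordance(tables: dict) -> pd.DataFrame:
    """Trend agreement of features shared across several volcano tables.

    Returns one row per shared m/z with each table's class and a
    ``concordant`` flag: True iff every table assigns the same non-ns
    class.  An empty intersection yields an empty frame with a warning.
    """
    if len(tables) < 2:
        raise WorkflowError("need at least 2 volcano tables")
    sets = [set(np.round(t.frame["mz"].to_numpy(), 6)) for t in tables.values()]
    shared = sorted(set.intersection(*sets))
    if not shared:
        log.warning("marker_concordance: no shared features between tables")
        return pd.DataFrame()
    rows = []
    for mz in shared:
        classes = {}
        for name, table in tables.items():
            match = table.frame[np.round(table.frame["mz"], 6) == mz]
            classes[name] = match["class"].iloc[0]
        values = list(classes.values())
        rows.append({"mz": mz, **classes,
                     "concordant": values[0] != NS and len(set(values)) == 1})
    return pd.DataFrame(rows)


def volcano_plot(table: VolcanoTable, ax=None, annotate_top: int = 5):
    """Basic volcano rendering: D versus -log10 adjusted p."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    frame = table.frame
    colors = frame["class"].map({UP: "crimson", DOWN: "teal", NS: "0.6"})
    logp = -np.log10(np.clip(frame["p_adj"], 1e-300, None))
    ax.scatter(frame["cohens_d"], logp, c=colors, s=12)
    ax.axvline(table.d_threshold, ls="--", lw=0.8, c="0.4")
    ax.axvline(-table.d_threshold, ls="--", lw=0.8, c="0.4")
    ax.axhline(-np.log10(table.p_threshold), ls="--", lw=0.8, c="0.4")
    for _, row in frame[frame["class"] != NS].nlargest(annotate_top, "cohens_d").iterrows():
        ax.annotate(f"{row['mz']:.2f}", (row["cohens_d"], -np.log10(max(row["p_adj"], 1e-300))),
                    fontsize=7)
    ax.set_xlabel(f"Cohen's D ({table.sign_convention})")
    ax.set_ylabel("-log10 adjusted p")
    return ax
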