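"""Transcriptome-wide bimodality scan and marker-candidate selection.

Probe sets whose expression is switched on or off by the donor's haplotype
show a two-mode intensity distribution across unrelated donors.  The scan
computes the dip statistic of every probe set's log2 intensities, converts
it to an empirical p-value against a shared Monte-Carlo null for the
dataset's sample count, applies Benjamini-Hochberg adjustment across probe
sets, and keeps candidates with small raw empirical p (default < 0.001)
whose minor expression mode is populated by at least a configurable floor
fraction of samples (default 5%, so single outliers do not masquerade as
haplotype markers).

For each candidate a working intensity threshold is proposed: the midpoint
of the two cluster centres of the best 1-D two-group split (exhaustive over
sorted split points, minimising within-group variance).  For probe sets
without evidence of bimodality the suggestion falls back to the median and
is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from hlascore.dip import bh_adjust, compute_dip, empirical_pvalue, get_null_distribution
from hlascore.preprocess import spread_90

RESULT_COLUMNS = [
    "probe_id",
    "dip",
    "empirical_p",
    "adjusted_p",
    "minor_mode_fraction",
    "suggested_threshold_log2",
    "threshold_fallback",
    "spread_90",
]


def minor_mode_fraction(values, threshold: float) -> float:
    """Fraction of samples in the minor expression mode.

    ``min(f, 1 - f)`` where ``f`` is the fraction of values strictly above
    the threshold; stands in for the minor-allele frequency of the
    polymorphism driving the two modes.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    x = np.asarray(values, dtype=float).ravel()
    f = float(np.mean(x > threshold))
    return min(f, 1.0 - f)


@dataclass(frozen=True)
class ThresholdSuggestion:
    threshold: float
    fallback: bool  # True when the values show no evidence of bimodality


def suggest_threshold(
    values,
    unimodal_p: float | None = None,
    p_cutoff: float = 0.05,
    n_sims: int = 2000,
    seed: int = 0,
) -> ThresholdSuggestion:
    """Propose a scoring threshold between the two expression modes.

    The threshold is the midpoint of the two group means at the exhaustive
    best two-group split of the sorted values (1-D k-means with k=2).  When
    the dip's empirical p-value ``unimodal_p`` (computed here if not
    supplied) is above ``p_cutoff`` there is no meaningful valley, and the
    median is returned with ``fallback=True``.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError("threshold suggestion needs at least 10 values")
    if unimodal_p is None:
        null = get_null_distribution(n, n_sims, seed)
        unimodal_p = empirical_pvalue(compute_dip(x), null).p
    if unimodal_p >= p_cutoff:
        return ThresholdSuggestion(threshold=float(np.median(x)), fallback=True)

    # exhaustive split: prefix sums give each split's within-group SS
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    k = np.arange(1, n)
    ss_left = c2[k - 1] - c1[k - 1] ** 2 / k
    ss_right = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    best = int(np.argmin(ss_left + ss_right)) + 1
    mid = 0.5 * (x[:best].mean() + x[best:].mean())
    return ThresholdSuggestion(threshold=float(mid), fallback=False)


class BimodalMarkerScanner(SelectorMixin, BaseEstimator):
    """Scan features (probe sets) of an expression matrix for bimodality.

    Parameters
    ----------
    n_sims : int, default=1_000_000
        Monte-Carlo draws for the null dip distribution (shared across all
        features; one null per dataset sample count).
    alpha : float, default=0.001
        Selection cut on the raw empirical p-value; the BH-adjusted p is
        reported alongside.
    minority_floor : float, default=0.05
        Minimum minor-mode fraction for a candidate.
    seed : int, default=0
        Seed of the null simulation; recorded in the results.
    log2_input : bool, default=False
        Set to True when ``X`` is already on the log2 scale; otherwise
        intensities are floored at ``floor`` and log2-transformed.

    Attributes
    ----------
    results_ : DataFrame with one row per feature (dip, empirical_p,
        adjusted_p, minor_mode_fraction, suggested_threshold_log2,
        threshold_fallback, spread_90), in input feature order.
    candidates_ : the selected rows of ``results_``, ranked by ascending
        empirical_p, then descending dip, then probe_id.
    support_mask_ : boolean mask of selected features.
    """

    def __init__(
        self,
        n_sims: int = 1_000_000,
        alpha: float = 0.001,
        minority_floor: float = 0.05,
        seed: int = 0,
        log2_input: bool = False,
        floor: float = 1.0,
        include: tuple = (),
    ):
        self.n_sims = n_sims
        self.alpha = alpha
        self.minority_floor = minority_floor
        self.seed = seed
        self.log2_input = log2_input
        self.floor = floor
        self.include = include

    def fit(self, X, y=None):
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        X = validate_data(self, X, ensure_min_samples=5)
        n_samples, n_probes = X.shape
        if feature_names is None:
            feature_names = [f"probe_{i}" for i in range(n_probes)]
        logx = X if self.log2_input else np.log2(np.maximum(X, self.floor))

        null = get_null_distribution(n_samples, self.n_sims, self.seed)
        rows = []
        for j in range(n_probes):
            vals = logx[:, j]
            dres = compute_dip(vals)
            ep = empirical_pvalue(dres, null)
            sug = suggest_threshold(vals, unimodal_p=ep.p)
            rows.append(
                (
                    feature_names[j],
                    dres.dip,
                    ep.p,
                    np.nan,  # adjusted below
                    minor_mode_fraction(vals, sug.threshold),
                    sug.threshold,
                    sug.fallback,
                    spread_90(vals, log2=False),
                )
            )
        results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        results["adjusted_p"] = bh_adjust(results["empirical_p"].to_numpy())

        selected = (results["empirical_p"] < self.alpha) & (
            results["minor_mode_fraction"] >= self.minority_floor
        )
        results["included_by_user"] = results["probe_id"].isin(set(self.include))
        selected |= results["included_by_user"]

        self.results_ = results
        self.support_mask_ = selected.to_numpy()
        self.candidates_ = (
            results[selected]
            .sort_values(
                ["empirical_p", "dip", "probe_id"],
                ascending=[True, False, True],
                kind="stable",
            )
            .reset_index(drop=True)
        )
        self.n_samples_ = n_samples
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_


@dataclass(frozen=True)
class ScanResult:
    """Ranked candidate list plus the scan's effective configuration."""

    candidates: pd.DataFrame = field(repr=False)
    results: pd.DataFrame = field(repr=False)
    n_sims: int
    seed: int
    alpha: float
    n_samples: int


def scan_bimodal(
    matrix: pd.DataFrame,
    n_sims: int = 1_000_000,
    alpha: float = 0.001,
    seed: int = 0,
    minority_floor: float = 0.05,
    include: tuple = (),
    log2_input: bool = False,
) -> ScanResult:
    """Bimodality scan of a probes x samples matrix of linear intensities.

    Thin wrapper over :class:`BimodalMarkerScanner` (which follows the
    scikit-learn samples x features orientation).
    """
    scanner = BimodalMarkerScanner(
        n_sims=n_sims,
        alpha=alpha,
        minority_floor=minority_floor,
        seed=seed,
        include=tuple(include),
        log2_input=log2_input,
    )
    scanner.fit(matrix.T)
    return ScanResult(
        candidates=scanner.candidates_,
        results=scanner.results_,
        n_sims=n_sims,
        seed=seed,
        alpha=alpha,
        n_samples=scanner.n_samples_,
    )
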