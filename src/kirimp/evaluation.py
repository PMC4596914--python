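"""Accuracy assessment: cross-validation, per-allele metrics, calibration,
credible intervals, threshold curves, and expected per-individual accuracy.

Accuracy proportions carry 95% equal-tailed credible intervals from a
binomial model with a uniform prior, i.e. quantiles of the
Beta(n_correct + 1, n - n_correct + 1) posterior.  Under cross-validation the
independence assumption behind the binomial model does not hold exactly
(training folds overlap), so those intervals are approximate; for independent
validation cohorts they are well founded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forest import ForestParams
from .imputation import (
    CallPolicy,
    ImputationResult,
    KirImputationModel,
    apply_threshold,
)
from .panel_io import KirTypeTable, ReferencePanel

__all__ = [
    "AccuracyReport",
    "credible_interval",
    "cross_validate",
    "per_allele_metrics",
    "calibration",
    "accuracy_vs_callrate",
    "expected_individual_accuracy",
]


@dataclass
class AccuracyReport:
    """Accuracy of MAP calls at one locus with its credible interval."""

    locus: str
    unit: str
    n: int
    n_correct: int
    accuracy: float
    ci_low: float
    ci_high: float


def credible_interval(n_correct: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed Beta(n_correct+1, n-n_correct+1) posterior interval.

    Binomial likelihood with a uniform (Beta(1,1)) prior on the accuracy.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= n_correct <= n):
        raise ValueError("n_correct must lie in [0, n]")
    alpha = (1.0 - level) / 2.0
    dist = stats.beta(n_correct + 1, n - n_correct + 1)
    return float(dist.ppf(alpha)), float(dist.ppf(1.0 - alpha))


def _report(locus: str, unit: str, correct: np.ndarray) -> AccuracyReport:
    n = int(correct.size)
    k = int(correct.sum())
    lo, hi = credible_interval(k, n)
    return AccuracyReport(locus=locus, unit=unit, n=n, n_correct=k,
                          accuracy=k / n, ci_low=lo, ci_high=hi)


def cross_validate(
    panel: ReferencePanel,
    params: ForestParams | None = None,
    loci: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict[str, AccuracyReport], dict[str, ImputationResult]]:
    """k-fold cross-validation of the per-locus imputation models.

    Haplotypes are shuffled with ``seed`` and split into k near-equal folds;
    each fold is imputed by a model trained on the others.  Returns per-locus
    accuracy reports and the pooled per-haplotype results (rows in original
    panel order).  A class absent from some training fold merely cannot be
    predicted in that fold — it is not an error.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    params = params if params is not None else ForestParams()
    loci = list(loci) if loci is not None else list(panel.kir_types.loci)
    n = panel.n_haplotypes
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    pooled_proba: dict[str, list] = {locus: [None] * n for locus in loci}
    pooled_classes: dict[str, list] = {}
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
        train_panel = ReferencePanel(
            haplotypes=panel.haplotypes.subset_haplotypes(train_idx),
            kir_types=KirTypeTable(
                unit="haplotype",
                values=panel.kir_types.values.iloc[train_idx],
            ),
        )
        fold_params = ForestParams(
            n_trees=params.n_trees, m_try=params.m_try,
            max_nodes=params.max_nodes, seed=(params.seed * 31 + f) % (2**31),
        )
        results = KirImputationModel(train_panel, loci=loci, params=fold_params).fit()
        test_haps = panel.haplotypes.subset_haplotypes(test_idx)
        imputed = results.impute(test_haps)
        for locus in loci:
            res = imputed[locus]
            pooled_classes.setdefault(locus, []).append(res.classes)
            for row, i in enumerate(test_idx):
                pooled_proba[locus][i] = (res.classes, res.proba[row])

    reports: dict[str, AccuracyReport] = {}
    pooled: dict[str, ImputationResult] = {}
    hap_ids = list(panel.haplotypes.haplotype_ids)
    for locus in loci:
        all_classes = np.unique(np.concatenate(pooled_classes[locus]))
        proba = np.zeros((n, len(all_classes)))
        for i, (cls, p) in enumerate(pooled_proba[locus]):
            idx = np.searchsorted(all_classes, cls)
            proba[i, idx] = p
        res = ImputationResult(locus=locus, unit_ids=hap_ids,
                               classes=all_classes, proba=proba)
        truth = _truth_array(panel, locus)
        correct = res.map_call == truth
        reports[locus] = _report(locus, "haplotype", correct)
        pooled[locus] = res
    return reports, pooled


def _truth_array(panel: ReferencePanel, locus: str) -> np.ndarray:
    col = panel.locus_labels(locus)
    from .panel_io import COPY_NUMBER_LOCI

    if locus in COPY_NUMBER_LOCI:
        return col.astype(int).to_numpy()
    return col.astype(str).to_numpy()


def per_allele_metrics(calls: Sequence, truth: Sequence, locus: str = "") -> pd.DataFrame:
    """Per-allele sensitivity and positive predictive value.

    sensitivity(a) = #(call=a and truth=a) / #(truth=a);
    ppv(a) = #(call=a and truth=a) / #(call=a).  A denominator of zero yields
    NaN with the corresponding ``*_defined`` flag False.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must align")
    alleles = np.unique(np.concatenate([calls, truth]))
    rows = []
    for a in alleles:
        n_truth = int((truth == a).sum())
        n_call = int((calls == a).sum())
        n_tp = int(((calls == a) & (truth == a)).sum())
        rows.append({
            "locus": locus,
            "allele": a,
            "count_in_panel": n_truth,
            "sensitivity": n_tp / n_truth if n_truth else np.nan,
            "sensitivity_defined": n_truth > 0,
            "ppv": n_tp / n_call if n_call else np.nan,
            "ppv_defined": n_call > 0,
        })
    return pd.DataFrame(rows)


def calibration(
    results: Mapping[str, ImputationResult] | ImputationResult,
    truth: Mapping[str, Sequence] | Sequence,
    n_bins: int = 10,
    level: float = 0.95,
) -> pd.DataFrame:
    """Bin MAP probabilities and compare mean MAP with observed accuracy.

    Pools MAP calls (across loci when given mappings), splits the observed
    MAP range into ``n_bins`` equal-width bins, and reports per bin the mean
    MAP, count, observed accuracy and its credible interval.  Empty bins are
    reported with n=0.  A degenerate range (all MAPs equal) collapses to a
    single bin.
    """
    if isinstance(results, ImputationResult):
        results = {results.locus or "locus": results}
        truth = {next(iter(results)): truth}
    maps, corrects = [], []
    for locus, res in results.items():
        t = np.asarray(truth[locus])
        maps.append(res.map_prob)
        corrects.append(res.map_call == t)
    map_prob = np.concatenate(maps)
    correct = np.concatenate(corrects)
    if map_prob.size == 0:
        raise ValueError("no imputations to calibrate")
    lo, hi = float(map_prob.min()), float(map_prob.max())
    if hi - lo < 1e-12:
        edges = np.array([lo, hi])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, map_prob, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            rows.append({"bin": b, "bin_low": edges[b], "bin_high": edges[min(b + 1, len(edges) - 1)],
                         "mean_map": np.nan, "n": 0, "observed_accuracy": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        k = int(correct[mask].sum())
        ci = credible_interval(k, n, level)
        rows.append({"bin": b, "bin_low": edges[b], "bin_high": edges[min(b + 1, len(edges) - 1)],
                     "mean_map": float(map_prob[mask].mean()), "n": n,
                     "observed_accuracy": k / n, "ci_low": ci[0], "ci_high": ci[1]})
    return pd.DataFrame(rows)


def accuracy_vs_callrate(
    result: ImputationResult, truth: Sequence, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Accuracy over called units and call rate at each probability threshold."""
    truth = np.asarray(truth)
    rows = []
    for t in thresholds:
        tc = apply_threshold(result, CallPolicy(threshold=t))
        n_called = int(tc.called.sum())
        if n_called:
            correct = (result.map_call[tc.called] == truth[tc.called]).sum()
            acc = float(correct / n_called)
        else:
            acc = np.nan
        rows.append({"threshold": t, "call_rate": tc.call_rate,
                     "n_called": n_called, "accuracy": acc})
    return pd.DataFrame(rows)


def expected_individual_accuracy(
    calls: Sequence[int],
    truth: Sequence[int],
    seed: int = 0,
    n_pairings: int = 100,
) -> float:
    """Expected per-individual accuracy under random pairing of haplotypes.

    Repeatedly pairs the per-haplotype copy-number calls at random (without
    replacement, dropping one haplotype when the count is odd) and averages
    the fraction of pairs whose summed call equals the summed truth.
    """
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    n = calls.size
    if n < 2:
        raise ValueError("need at least two haplotypes")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_pairings)
    half = n // 2
    for r in range(n_pairings):
        perm = rng.permutation(n)[: 2 * half]
        a, b = perm[0::2], perm[1::2]
        accs[r] = np.mean((calls[a] + calls[b]) == (truth[a] + truth[b]))
    return float(accs.mean())
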