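"""SNP importance ranking, inclusion/exclusion experiments, and set selection.

The route from a dense SNP panel to a minimal informative set: rank SNPs by
permutation variable importance, iteratively remove the top-ranked SNP while
tracking the out-of-bag accuracy of models fitted to the remaining and to the
removed SNPs, choose a per-locus count of SNPs to take, union the choices
across loci, and drop SNPs flagged for poor intensity clustering.  Also
provides the single tag-SNP baseline (best simple classifier on the training
data) and the assessment of other genotyping arrays by intersecting their
manifests with the panel on GRCh37 coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .forest import ForestParams, fit_forest
from .panel_io import HaplotypePanel, PanelValidationError, ReferencePanel

__all__ = [
    "SelectionStep",
    "SelectedSnpSet",
    "TagSnp",
    "rank_snps",
    "removal_experiment",
    "suggest_counts",
    "build_selected_set",
    "best_tag_snp",
    "assess_array",
]


def _locus_y(panel: ReferencePanel, locus: str) -> np.ndarray:
    from .evaluation import _truth_array

    return _truth_array(panel, locus)


def rank_snps(
    panel: ReferencePanel,
    locus: str,
    params: ForestParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank the panel's SNPs by permutation importance for one locus.

    Returns a frame sorted by descending importance, ties broken by genomic
    position, with columns snp_id, position, importance, mean_drop, sd_drop.
    """
    params = params if params is not None else ForestParams()
    if seed is not None:
        params = ForestParams(n_trees=params.n_trees, m_try=params.m_try,
                              max_nodes=params.max_nodes, seed=seed)
    X = panel.haplotypes.alleles
    y = _locus_y(panel, locus)
    forest = fit_forest(X, y, params, snp_ids=panel.haplotypes.snp_ids)
    rng = np.random.default_rng(params.seed + 1)
    imp = forest.permutation_importance(X, y, rng)
    df = pd.DataFrame({
        "snp_id": panel.haplotypes.snp_ids,
        "position": panel.haplotypes.positions,
        "importance": imp.score,
        "mean_drop": imp.mean_drop,
        "sd_drop": imp.sd_drop,
    })
    return df.sort_values(["importance", "position"],
                          ascending=[False, True]).reset_index(drop=True)


@dataclass
class SelectionStep:
    """One step of the iterative removal experiment."""

    locus: str
    step: int
    removed_snp_id: str
    removed_snp_ids: list[str]        # all removed so far (k at step k)
    accuracy_remaining: float         # OOB accuracy of model on remaining SNPs
    accuracy_removed: float           # OOB accuracy of model on removed SNPs


def _oob_accuracy(panel: ReferencePanel, snp_idx: np.ndarray, locus: str,
                  params: ForestParams) -> float:
    sub = panel.haplotypes.subset_snps(snp_idx)
    y = _locus_y(panel, locus)
    forest = fit_forest(sub.alleles, y, params, snp_ids=sub.snp_ids)
    _, _, acc = forest.oob_predict(sub.alleles, y)
    return acc


def removal_experiment(
    panel: ReferencePanel,
    locus: str,
    params: ForestParams | None = None,
    max_steps: int | None = None,
    rerank: bool = True,
) -> list[SelectionStep]:
    """Iteratively remove the top-importance SNP, tracking both models' accuracy.

    At each step the current most important SNP moves from the remaining set
    to the removed set; a model is fitted to each set and its OOB accuracy
    recorded.  The removed-set model is fitted with m equal to the removed-set
    size (no attribute subsetting, so few SNPs are fully used).  With
    ``rerank=False``, the initial importance ranking is frozen instead of
    being recomputed after each removal.
    """
    params = params if params is not None else ForestParams()
    n_snps = panel.haplotypes.n_snps
    if n_snps < 2:
        raise PanelValidationError("need at least two SNPs")
    max_steps = max_steps if max_steps is not None else n_snps - 1
    snp_ids = panel.haplotypes.snp_ids
    id_to_idx = {s: i for i, s in enumerate(snp_ids)}
    remaining = list(range(n_snps))
    removed: list[int] = []
    frozen_order: list[int] | None = None
    if not rerank:
        ranking = rank_snps(panel, locus, params)
        frozen_order = [id_to_idx[s] for s in ranking["snp_id"]]
    steps: list[SelectionStep] = []
    for step in range(1, max_steps + 1):
        if len(remaining) < 2:
            break
        if rerank:
            sub_panel = ReferencePanel(
                haplotypes=panel.haplotypes.subset_snps(remaining),
                kir_types=panel.kir_types,
            )
            sub_params = ForestParams(
                n_trees=params.n_trees,
                m_try=min(params.resolve_m_try(n_snps), len(remaining)),
                max_nodes=params.max_nodes, seed=params.seed + step,
            )
            ranking = rank_snps(sub_panel, locus, sub_params)
            top_id = ranking["snp_id"].iloc[0]
        else:
            top_id = snp_ids[next(i for i in frozen_order if i in set(remaining))]
        top_idx = id_to_idx[top_id]
        remaining.remove(top_idx)
        removed.append(top_idx)
        rem_params = ForestParams(
            n_trees=params.n_trees,
            m_try=min(params.resolve_m_try(n_snps), len(remaining)),
            max_nodes=params.max_nodes, seed=params.seed + 5000 + step,
        )
        acc_rem = _oob_accuracy(panel, np.array(remaining), locus, rem_params)
        # removed-set model: m set to the full removed-set size
        out_params = ForestParams(
            n_trees=params.n_trees, m_try=len(removed),
            max_nodes=params.max_nodes, seed=params.seed + 9000 + step,
        )
        acc_out = _oob_accuracy(panel, np.array(removed), locus, out_params)
        steps.append(SelectionStep(
            locus=locus, step=step, removed_snp_id=top_id,
            removed_snp_ids=[snp_ids[i] for i in removed],
            accuracy_remaining=acc_rem, accuracy_removed=acc_out,
        ))
    return steps


def suggest_counts(
    experiments: Mapping[str, Sequence[SelectionStep]],
    full_accuracy: Mapping[str, float],
    tolerance: float = 0.01,
) -> dict[str, int]:
    """Convenience rule replacing the by-eye choice of per-locus SNP counts.

    For each locus, the smallest k such that the model on the k
    most-important (removed) SNPs reaches within ``tolerance`` (1 percentage
    point by default) of the full-panel OOB accuracy.
    """
    counts: dict[str, int] = {}
    for locus, steps in experiments.items():
        target = full_accuracy[locus] - tolerance
        chosen = len(steps)
        for s in steps:
            if s.accuracy_removed >= target:
                chosen = s.step
                break
        counts[locus] = chosen
    return counts


@dataclass
class SelectedSnpSet:
    """Union of per-locus top SNPs with poor-clustering SNPs excluded."""

    per_locus_counts: dict[str, int]
    snp_ids: list[str]              # final set, good clustering only
    excluded_poor: list[str]        # SNPs dropped by the clustering flag

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def build_selected_set(
    rankings: Mapping[str, Sequence[str]],
    per_locus_counts: Mapping[str, int],
    clustering_flags: Mapping[str, bool],
) -> SelectedSnpSet:
    """Take the top-count SNPs per locus, union them, drop poor-clustering SNPs.

    ``rankings`` maps locus -> SNP ids in descending importance;
    ``clustering_flags`` maps snp_id -> True when the SNP's intensity
    clustering was judged poor (a user-supplied visual-QC input).
    """
    union: list[str] = []
    seen: set[str] = set()
    for locus, count in per_locus_counts.items():
        ranked = list(rankings[locus])
        if count > len(ranked):
            raise ValueError(f"{locus}: requested {count} SNPs, only {len(ranked)} ranked")
        for s in ranked[:count]:
            if s not in seen:
                seen.add(s)
                union.append(s)
    if not union:
        raise ValueError("per-locus counts select no SNPs")
    kept = [s for s in union if not clustering_flags.get(s, False)]
    dropped = [s for s in union if clustering_flags.get(s, False)]
    return SelectedSnpSet(per_locus_counts=dict(per_locus_counts),
                          snp_ids=kept, excluded_poor=dropped)


@dataclass
class TagSnp:
    """Best single-SNP classifier for a locus on the training data."""

    locus: str
    snp_id: str
    position: int
    rule: dict[int, object]   # allele -> predicted class
    accuracy: float


def best_tag_snp(panel: ReferencePanel, locus: str) -> TagSnp:
    """Exhaustive search for the SNP whose simple classifier is most accurate.

    Each SNP's rule maps each allele to the majority class among training
    haplotypes carrying that allele; the SNP maximizing training accuracy
    wins (ties broken toward the smallest genomic position).  The accuracy
    criterion — not Pearson correlation — matches how models are compared.
    """
    X = panel.haplotypes.alleles
    y = _locus_y(panel, locus)
    classes, y_codes = np.unique(y, return_inverse=True)
    n, p = X.shape
    best = None
    for j in range(p):
        col = X[:, j]
        rule = {}
        correct = 0
        for allele in (0, 1):
            mask = col == allele
            if mask.any():
                counts = np.bincount(y_codes[mask], minlength=len(classes))
                maj = int(np.argmax(counts))
                rule[allele] = classes[maj]
                correct += int(counts[maj])
            else:
                rule[allele] = classes[int(np.argmax(np.bincount(y_codes)))]
        acc = correct / n
        pos = panel.haplotypes.snps[j].position
        key = (acc, -pos)
        if best is None or key > best[0]:
            best = (key, j, rule, acc)
    _, j, rule, acc = best
    snp = panel.haplotypes.snps[j]
    return TagSnp(locus=locus, snp_id=snp.snp_id, position=snp.position,
                  rule=rule, accuracy=acc)


def assess_array(
    panel: ReferencePanel,
    manifest_positions: Sequence[int],
    loci: Sequence[str],
    params: ForestParams | None = None,
) -> tuple[pd.DataFrame, int]:
    """Best-case accuracy using only SNPs present on a given array manifest.

    Intersects the manifest's GRCh37 positions with the panel's, refits each
    locus on the intersection, and reports per-locus OOB accuracy (assuming
    every intersecting SNP would be perfectly typed).
    """
    params = params if params is not None else ForestParams()
    positions = set(int(p) for p in manifest_positions)
    idx = np.array([j for j, s in enumerate(panel.haplotypes.snps)
                    if s.position in positions], dtype=int)
    if idx.size == 0:
        raise PanelValidationError("manifest shares no positions with the panel")
    sub_params = ForestParams(
        n_trees=params.n_trees,
        m_try=min(params.resolve_m_try(panel.haplotypes.n_snps), idx.size),
        max_nodes=params.max_nodes, seed=params.seed,
    )
    rows = []
    for locus in loci:
        acc = _oob_accuracy(panel, idx, locus, sub_params)
        rows.append({"locus": locus, "oob_accuracy": acc, "n_snps": int(idx.size)})
    return pd.DataFrame(rows), int(idx.size)
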