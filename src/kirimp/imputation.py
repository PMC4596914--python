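"""Per-locus model fitting and imputation: the Model/Results front of the package.

:class:`KirImputationModel` wraps a reference panel (phased SNP haplotypes
joined to per-haplotype KIR types) and a set of target loci; ``fit()`` trains
one random-forest classifier per locus and returns a
:class:`KirImputationResults` carrying the fitted forests, their out-of-bag
diagnostics, and the imputation methods: per-haplotype probability
distributions with MAP calls, probability-threshold calling, coarsening of
whole-haplotype calls to per-locus copy numbers, and per-individual
copy-number totals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .forest import Forest, ForestParams, fit_forest
from .panel_io import (
    COPY_NUMBER_LOCI,
    HAPLOTYPE_LOCUS,
    HaplotypePanel,
    PanelValidationError,
    ReferencePanel,
)

__all__ = [
    "KirImputationModel",
    "KirImputationResults",
    "ImputationResult",
    "CallPolicy",
    "ThresholdedCalls",
    "apply_threshold",
    "coarsen",
    "impute_individuals",
    "fit_locus_models",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class ImputationResult:
    """Per-unit probability distribution over one locus's type alleles."""

    locus: str
    unit_ids: list[str]
    classes: np.ndarray           # canonical (sorted) label order
    proba: np.ndarray             # (n_units, n_classes), rows sum to 1

    def __post_init__(self) -> None:
        self.proba = np.asarray(self.proba, dtype=float)
        if self.proba.shape != (len(self.unit_ids), len(self.classes)):
            raise ValueError("probability table shape mismatch")

    @property
    def map_call(self) -> np.ndarray:
        """MAP call per unit; ties broken toward the first (canonical) label."""
        if len(self.unit_ids) == 0:
            return np.array([], dtype=self.classes.dtype)
        return self.classes[np.argmax(self.proba, axis=1)]

    @property
    def map_prob(self) -> np.ndarray:
        if len(self.unit_ids) == 0:
            return np.array([], dtype=float)
        return self.proba.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proba, index=pd.Index(self.unit_ids),
                            columns=[str(c) for c in self.classes])


@dataclass(frozen=True)
class CallPolicy:
    """Probability-threshold calling: call retained iff MAP prob >= threshold."""

    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class ThresholdedCalls:
    """Calls surviving a probability threshold; uncalled units are missing."""

    locus: str
    unit_ids: list[str]
    calls: np.ndarray        # object array, None where not called
    called: np.ndarray       # bool mask
    call_rate: float


def apply_threshold(result: ImputationResult, policy: CallPolicy) -> ThresholdedCalls:
    """Retain MAP calls whose probability meets the threshold (>=)."""
    if len(result.unit_ids) == 0:
        return ThresholdedCalls(result.locus, [], np.array([], dtype=object),
                                np.array([], dtype=bool), float("nan"))
    called = result.map_prob >= policy.threshold
    calls = np.where(called, result.map_call, None)
    return ThresholdedCalls(
        locus=result.locus,
        unit_ids=list(result.unit_ids),
        calls=calls.astype(object),
        called=called,
        call_rate=float(called.mean()),
    )


def coarsen(
    hap_result: ImputationResult, copy_map: pd.DataFrame
) -> dict[str, ImputationResult]:
    """Push a whole-haplotype distribution forward to per-locus copy numbers.

    ``copy_map`` maps each whole-haplotype label (index) to its copy number at
    each locus (columns).  P(copy=c) at a locus is the summed probability of
    all haplotype labels mapping to c, so normalization is conserved exactly.
    """
    unmapped = [c for c in hap_result.classes if c not in copy_map.index]
    if unmapped:
        raise ValueError(f"labels missing from the copy map: {unmapped}")
    out: dict[str, ImputationResult] = {}
    for locus in copy_map.columns:
        copies = copy_map.loc[list(hap_result.classes), locus].to_numpy().astype(int)
        classes = np.unique(copies)
        proba = np.zeros((len(hap_result.unit_ids), len(classes)))
        for k, c in enumerate(classes):
            proba[:, k] = hap_result.proba[:, copies == c].sum(axis=1)
        out[locus] = ImputationResult(
            locus=locus, unit_ids=list(hap_result.unit_ids),
            classes=classes, proba=proba,
        )
    return out


def impute_individuals(
    results: Mapping[str, ImputationResult],
    pairs: Sequence[tuple[int, int]] | None = None,
    mode: str = "sum_of_map",
) -> pd.DataFrame:
    """Combine per-haplotype copy-number results into per-individual totals.

    Haplotypes are paired in input order unless explicit index ``pairs`` are
    given.  ``mode='sum_of_map'`` (default) sums the two per-haplotype MAP
    copy numbers; ``mode='map_of_sum'`` convolves the two distributions and
    takes the MAP of the total — exposed as an alternative since either
    convention is defensible for unphased validation.
    Returns a tidy frame: individual, locus, call, probability.
    """
    rows = []
    for locus, res in results.items():
        n = len(res.unit_ids)
        if pairs is None:
            if n % 2 != 0:
                raise ValueError(f"{locus}: odd haplotype count; supply explicit pairs")
            pair_list = [(i, i + 1) for i in range(0, n, 2)]
        else:
            pair_list = list(pairs)
        copies = res.classes.astype(int)
        for pi, (i, j) in enumerate(pair_list):
            if mode == "sum_of_map":
                call = int(copies[np.argmax(res.proba[i])]) + int(copies[np.argmax(res.proba[j])])
                prob = float(res.proba[i].max() * res.proba[j].max())
            elif mode == "map_of_sum":
                conv: dict[int, float] = {}
                for a, pa in zip(copies, res.proba[i]):
                    for b, pb in zip(copies, res.proba[j]):
                        conv[a + b] = conv.get(a + b, 0.0) + pa * pb
                call, prob = max(conv.items(), key=lambda kv: (kv[1], -kv[0]))
            else:
                raise ValueError(f"unknown mode {mode!r}")
            rows.append({"individual": pi, "locus": locus, "call": call,
                         "probability": prob})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


class KirImputationModel:
    """Specification of a per-locus imputation fit on a reference panel.

    Parameters
    ----------
    panel
        Reference panel: phased haplotypes with per-haplotype KIR types.
    loci
        Target loci to fit (default: every locus present in the panel's
        type table).
    params
        Forest hyperparameters shared across loci (seeds are derived
        per locus so forests are independent but reproducible).
    """

    def __init__(
        self,
        panel: ReferencePanel,
        loci: Sequence[str] | None = None,
        params: ForestParams | None = None,
    ):
        self.panel = panel
        self.loci = list(loci) if loci is not None else list(panel.kir_types.loci)
        for locus in self.loci:
            if locus not in panel.kir_types.values.columns:
                raise PanelValidationError(f"locus {locus!r} absent from panel")
        self.params = params if params is not None else ForestParams()
        if panel.haplotypes.has_missing():
            raise PanelValidationError(
                "panel contains missing alleles; impute or drop them before fitting"
            )

    def fit(self) -> "KirImputationResults":
        """Train one forest per locus. Deterministic given ``params.seed``."""
        X = self.panel.haplotypes.alleles
        snp_ids = self.panel.haplotypes.snp_ids
        forests: dict[str, Forest] = {}
        for i, locus in enumerate(self.loci):
            y = _locus_target(self.panel, locus)
            locus_params = ForestParams(
                n_trees=self.params.n_trees,
                m_try=self.params.m_try,
                max_nodes=self.params.max_nodes,
                seed=(self.params.seed * 10007 + i) % (2**31),
            )
            forests[locus] = fit_forest(X, y, locus_params, snp_ids=snp_ids)
        return KirImputationResults(
            model=self, forests=forests, snp_ids=snp_ids,
            snps=list(self.panel.haplotypes.snps),
        )


def _locus_target(panel: ReferencePanel, locus: str) -> np.ndarray:
    col = panel.locus_labels(locus)
    if col.isna().any():
        raise PanelValidationError(f"{locus}: missing type labels in panel")
    if locus in COPY_NUMBER_LOCI:
        return col.astype(int).to_numpy()
    return col.astype(str).to_numpy()


class KirImputationResults:
    """Fitted per-locus forests plus imputation and diagnostic methods."""

    def __init__(self, model: KirImputationModel | None, forests: dict[str, Forest],
                 snp_ids: list[str], snps=None):
        self.model = model
        self.forests = forests
        self.snp_ids = snp_ids
        self.snps = snps
        self._oob_cache: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}

    @property
    def loci(self) -> list[str]:
        return list(self.forests)

    # -- imputation ---------------------------------------------------------

    def impute(self, haplotypes: HaplotypePanel) -> dict[str, ImputationResult]:
        """Impute every fitted locus for new phased haplotypes.

        The input SNP set must cover the model's (align coding first with
        :func:`kirimp.panel_io.align_alleles` when panels differ).
        """
        self._check_alignment(haplotypes)
        out: dict[str, ImputationResult] = {}
        ids = list(haplotypes.haplotype_ids)
        X = haplotypes.alleles
        in_ids = haplotypes.snp_ids
        for locus, forest in self.forests.items():
            if len(ids) == 0:
                proba = np.zeros((0, forest.n_classes))
            else:
                proba = forest.predict_proba(X, snp_ids=in_ids)
            out[locus] = ImputationResult(
                locus=locus, unit_ids=ids, classes=forest.classes, proba=proba
            )
        return out

    def _check_alignment(self, haplotypes: HaplotypePanel) -> None:
        if self.snps is None:
            return
        by_pos = {s.position: s for s in haplotypes.snps}
        for s in self.snps:
            q = by_pos.get(s.position)
            if q is None:
                raise PanelValidationError(
                    f"input lacks model SNP {s.snp_id} at {s.position}; "
                    "run align_alleles against the training panel first"
                )
            if (q.allele1, q.allele2) != (s.allele1, s.allele2):
                raise PanelValidationError(
                    f"allele coding mismatch at {s.snp_id} "
                    f"({q.allele1}/{q.allele2} vs {s.allele1}/{s.allele2}); "
                    "run align_alleles against the training panel first"
                )

    # -- OOB diagnostics ----------------------------------------------------

    def oob(self, locus: str) -> tuple[np.ndarray, np.ndarray, float]:
        """(OOB probability table, coverage mask, OOB accuracy) for one locus."""
        if locus not in self._oob_cache:
            if self.model is None:
                raise ValueError("OOB diagnostics need the training panel")
            X = self.model.panel.haplotypes.alleles
            y = _locus_target(self.model.panel, locus)
            self._oob_cache[locus] = self.forests[locus].oob_predict(X, y)
        return self._oob_cache[locus]

    def oob_accuracy(self) -> pd.Series:
        return pd.Series({locus: self.oob(locus)[2] for locus in self.loci},
                         name="oob_accuracy")

    def oob_results(self) -> dict[str, ImputationResult]:
        """OOB distributions as ImputationResults restricted to covered rows."""
        out = {}
        for locus in self.loci:
            proba, covered, _ = self.oob(locus)
            ids = [h for h, c in zip(self.model.panel.haplotypes.haplotype_ids, covered) if c]
            out[locus] = ImputationResult(
                locus=locus, unit_ids=ids,
                classes=self.forests[locus].classes, proba=proba[covered],
            )
        return out

    def summary(self) -> str:
        """Human-readable per-locus fit summary (OOB accuracy and classes)."""
        lines = [
            "KIR imputation model",
            "=" * 60,
            f"loci: {len(self.loci)}   SNPs: {len(self.snp_ids)}   "
            f"trees/locus: {next(iter(self.forests.values())).params.n_trees}",
            "-" * 60,
            f"{'locus':<16}{'classes':>8}{'oob_accuracy':>14}",
        ]
        for locus in self.loci:
            forest = self.forests[locus]
            try:
                acc = f"{self.oob(locus)[2]:.3f}"
            except ValueError:
                acc = "n/a"
            lines.append(f"{locus:<16}{forest.n_classes:>8}{acc:>14}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write a versioned, self-describing JSON model file."""
        doc = {
            "format": "kirimp-model",
            "version": MODEL_FORMAT_VERSION,
            "snp_ids": self.snp_ids,
            "snps": [
                {"snp_id": s.snp_id, "position": s.position,
                 "allele1": s.allele1, "allele2": s.allele2}
                for s in (self.snps or [])
            ],
            "forests": {locus: f.to_dict() for locus, f in self.forests.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "KirImputationResults":
        from .panel_io import SnpDefinition

        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "kirimp-model":
            raise ValueError(f"{path}: not a kirimp model file")
        if doc.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported model version {doc.get('version')}")
        forests = {locus: Forest.from_dict(d) for locus, d in doc["forests"].items()}
        snps = [SnpDefinition(**s) for s in doc.get("snps", [])] or None
        return cls(model=None, forests=forests, snp_ids=doc["snp_ids"], snps=snps)


def fit_locus_models(
    panel: ReferencePanel,
    loci: Sequence[str] | None = None,
    params: ForestParams | None = None,
) -> KirImputationResults:
    """Functional wrapper: build the model and fit it in one call."""
    return KirImputationModel(panel, loci=loci, params=params).fit()
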