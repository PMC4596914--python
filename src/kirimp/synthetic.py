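"""Synthetic KIR-region data with known truth.

The generative model mirrors the structural biology of the region: each
haplotype is a pair of gene-content motifs — one centromeric, one telomeric —
joined at the reciprocal recombination hotspot between KIR3DP1 and KIR2DL4.
Per-locus copy numbers are deterministic given the motif pair, the
whole-haplotype class (``KIRhaplotype``) is the motif-pair name, and ``AvsB``
is A exactly when the haplotype is composed of the designated A motifs
(cA01 + tA01).  SNPs on each side of the hotspot tag that side's motif with a
configurable strength; independent flip noise emulates genotyping error.

Defaults emulate European-ancestry motif frequencies (cA01/cB01/cB02 at
0.55/0.35/0.10; tA01/tB01 at 0.60/0.40) with 150 SNPs per side,
mirroring the ~300-SNP density of a dense immune-region genotyping array
over the 400 kb KIR region.  A long-tail
preset adds rare motifs so that training-allele counts span from under 10 to
well over 100 copies, for accuracy-vs-frequency experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import (
    ALL_LOCI,
    AVSB_LOCUS,
    COPY_NUMBER_LOCI,
    HAPLOTYPE_LOCUS,
    HaplotypePanel,
    KirTypeTable,
    ReferencePanel,
    SnpDefinition,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "default_spec",
    "long_tail_spec",
    "simulate_panel",
    "simulate_families",
    "simulate_validation_cohort",
]

# Gene content of the common motifs (copies contributed per locus).  Framework
# loci KIR3DP1 (centromeric boundary) and KIR2DL4 (telomeric boundary) are on
# every motif; KIR2DL5 can sit on both sides, so copy numbers add across the
# hotspot.
CEN_CONTENT = {
    "cA01": {"KIR2DL3": 1, "KIR2DP1": 1, "KIR2DL1": 1, "KIR3DP1": 1},
    "cB01": {
        "KIR2DS2": 1, "KIR2DL2": 1, "KIR2DL5": 1, "KIR2DS3": 1,
        "KIR2DP1": 1, "KIR2DL1": 1, "KIR3DP1": 1,
    },
    "cB02": {"KIR2DS2": 1, "KIR2DL2": 1, "KIR3DP1": 1},
}
TEL_CONTENT = {
    "tA01": {
        "KIR2DL4": 1, "KIR3DL1ex4": 1, "KIR3DL1ex9": 1,
        "KIR2DS4TOTAL": 1, "KIR2DS4WT": 1,
    },
    "tB01": {
        "KIR2DL4": 1, "KIR3DS1": 1, "KIR2DL5": 1, "KIR2DS5": 1, "KIR2DS1": 1,
    },
}
A_MOTIFS = ("cA01", "tA01")

_CEN_REGION = (55_100_000, 55_290_000)
_TEL_REGION = (55_310_000, 55_500_000)


@dataclass
class SyntheticSpec:
    """Generative parameters for the synthetic KIR region."""

    cen_freqs: dict[str, float]
    tel_freqs: dict[str, float]
    cen_content: dict[str, dict[str, int]]
    tel_content: dict[str, dict[str, int]]
    n_snps_cen: int = 150
    n_snps_tel: int = 150
    tagging_strength: float = 0.95
    error_rate: float = 0.005
    n_haplotypes: int = 500
    linkage: float = 0.0  # 0 = free recombination at the hotspot
    seed: int = 0

    def __post_init__(self) -> None:
        for name, freqs in (("centromeric", self.cen_freqs), ("telomeric", self.tel_freqs)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} motif frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{name} motif frequencies must be non-negative")
        if not (0.5 <= self.tagging_strength <= 1.0):
            raise ValueError("tagging_strength must lie in [0.5, 1]")
        if not (0.0 <= self.error_rate <= 0.5):
            raise ValueError("error_rate must lie in [0, 0.5]")
        if self.n_snps_cen < len(self.cen_freqs) or self.n_snps_tel < len(self.tel_freqs):
            raise ValueError("need at least one SNP per motif on each side")
        if not (0.0 <= self.linkage <= 1.0):
            raise ValueError("linkage must lie in [0, 1]")

    @property
    def hotspot_index(self) -> int:
        """SNP column index of the first telomeric SNP."""
        return self.n_snps_cen

    @property
    def n_snps(self) -> int:
        return self.n_snps_cen + self.n_snps_tel

    def copy_map(self) -> pd.DataFrame:
        """Motif-pair label -> copy number at each of the 17 loci (total map)."""
        rows = {}
        for cm in self.cen_freqs:
            for tm in self.tel_freqs:
                label = f"{cm}-{tm}"
                rows[label] = {
                    locus: self.cen_content.get(cm, {}).get(locus, 0)
                    + self.tel_content.get(tm, {}).get(locus, 0)
                    for locus in COPY_NUMBER_LOCI
                }
        return pd.DataFrame.from_dict(rows, orient="index")[list(COPY_NUMBER_LOCI)]


@dataclass
class SyntheticTruth:
    """Per-haplotype ground truth emitted alongside a simulated panel."""

    haplotype_ids: list[str]
    cen_motif: list[str]
    tel_motif: list[str]
    kir_types: KirTypeTable  # 17 loci + KIRhaplotype + AvsB, unit=haplotype

    def labels(self, locus: str) -> pd.Series:
        return self.kir_types.values[locus]


def default_spec(**overrides) -> SyntheticSpec:
    """European-like study conditions: 3 centromeric and 2 telomeric motifs."""
    kwargs = dict(
        cen_freqs={"cA01": 0.55, "cB01": 0.35, "cB02": 0.10},
        tel_freqs={"tA01": 0.60, "tB01": 0.40},
        cen_content=CEN_CONTENT,
        tel_content=TEL_CONTENT,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def long_tail_spec(n_rare: int = 5, tail: float = 0.5, **overrides) -> SyntheticSpec:
    """Add geometrically rare centromeric motifs so allele counts span <10 to >100.

    Rare motif ``cR{i}`` gets frequency proportional to ``tail**i``; the
    common motifs keep the default ratios within the remaining mass.  Rare
    motif gene content is a perturbation of cB02.
    """
    rng = np.random.default_rng(2024)
    rare_mass = 0.06
    weights = np.array([tail**i for i in range(n_rare)])
    rare = {f"cR{i:02d}": rare_mass * w / weights.sum() for i, w in enumerate(weights)}
    common_mass = 1.0 - rare_mass
    cen = {"cA01": 0.55 * common_mass, "cB01": 0.35 * common_mass,
           "cB02": 0.10 * common_mass, **rare}
    content = {k: dict(v) for k, v in CEN_CONTENT.items()}
    for name in rare:
        base = dict(CEN_CONTENT["cB02"])
        flip = rng.choice(["KIR2DS3", "KIR2DP1", "KIR2DL1", "KIR2DL5"])
        base[flip] = base.get(flip, 0) + 1
        content[name] = base
    kwargs = dict(
        cen_freqs=cen,
        tel_freqs={"tA01": 0.60, "tB01": 0.40},
        cen_content=content,
        tel_content=TEL_CONTENT,
        n_snps_cen=max(150, len(cen)),
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


# ---------------------------------------------------------------------------


def _tag_subsets(motifs: list[str], n_snps: int, rng: np.random.Generator) -> list[frozenset]:
    """Assign each SNP the motif subset whose members carry its '1' allele.

    The first len(motifs) SNPs are one-vs-rest tags (so every motif pair is
    separable); the rest get random non-trivial subsets.
    """
    subsets = [frozenset({m}) for m in motifs]
    n_m = len(motifs)
    while len(subsets) < n_snps:
        size = int(rng.integers(1, n_m)) if n_m > 1 else 1
        subsets.append(frozenset(rng.choice(motifs, size=size, replace=False)))
    return subsets[:n_snps]


def _make_snp_defs(spec: SyntheticSpec) -> list[SnpDefinition]:
    defs = []
    cen_pos = np.linspace(*_CEN_REGION, spec.n_snps_cen).astype(int)
    tel_pos = np.linspace(*_TEL_REGION, spec.n_snps_tel).astype(int)
    for i, p in enumerate(cen_pos):
        defs.append(SnpDefinition(snp_id=f"cen{i:03d}", position=int(p),
                                  allele1="A", allele2="G"))
    for i, p in enumerate(tel_pos):
        defs.append(SnpDefinition(snp_id=f"tel{i:03d}", position=int(p),
                                  allele1="A", allele2="C"))
    return defs


def _draw_motifs(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    cen_names = list(spec.cen_freqs)
    tel_names = list(spec.tel_freqs)
    cen = rng.choice(len(cen_names), size=n, p=list(spec.cen_freqs.values()))
    tel = rng.choice(len(tel_names), size=n, p=list(spec.tel_freqs.values()))
    if spec.linkage > 0:
        # correlated pairing: with prob `linkage`, the telomeric motif copies
        # the A/B character of the centromeric one
        for i in range(n):
            if rng.random() < spec.linkage:
                is_a = cen_names[cen[i]] == A_MOTIFS[0]
                tel[i] = tel_names.index(A_MOTIFS[1]) if is_a else \
                    next(j for j, t in enumerate(tel_names) if t != A_MOTIFS[1])
    return np.array(cen_names)[cen], np.array(tel_names)[tel]


def _alleles_for(spec: SyntheticSpec, cen: np.ndarray, tel: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    n = len(cen)
    cen_subsets = _tag_subsets(list(spec.cen_freqs), spec.n_snps_cen,
                               np.random.default_rng(spec.seed + 101))
    tel_subsets = _tag_subsets(list(spec.tel_freqs), spec.n_snps_tel,
                               np.random.default_rng(spec.seed + 202))
    X = np.zeros((n, spec.n_snps), dtype=np.int8)
    for j, sub in enumerate(cen_subsets):
        X[:, j] = np.isin(cen, list(sub)).astype(np.int8)
    for j, sub in enumerate(tel_subsets):
        X[:, spec.hotspot_index + j] = np.isin(tel, list(sub)).astype(np.int8)
    # imperfect tagging, then genotyping error; both are independent flips
    tag_noise = rng.random(X.shape) > spec.tagging_strength
    geno_err = rng.random(X.shape) < spec.error_rate
    flip = tag_noise ^ geno_err
    X[flip] = 1 - X[flip]
    return X


def _truth_table(spec: SyntheticSpec, hap_ids: list[str], cen: np.ndarray,
                 tel: np.ndarray) -> KirTypeTable:
    cmap = spec.copy_map()
    labels = [f"{c}-{t}" for c, t in zip(cen, tel)]
    values = cmap.loc[labels].reset_index(drop=True)
    values.index = pd.Index(hap_ids)
    values = values.astype("Int64")
    values[HAPLOTYPE_LOCUS] = labels
    values[AVSB_LOCUS] = [
        "A" if (c, t) == A_MOTIFS else "B" for c, t in zip(cen, tel)
    ]
    return KirTypeTable(unit="haplotype", values=values[list(ALL_LOCI)])


def simulate_panel(
    spec: SyntheticSpec, seed: int | None = None, n: int | None = None,
    id_prefix: str = "hap",
) -> tuple[ReferencePanel, SyntheticTruth, pd.DataFrame]:
    """Draw a reference panel of haplotypes with full truth.

    Returns ``(panel, truth, copy_map)`` where the copy map sends each
    ``KIRhaplotype`` label to its 17-locus copy-number vector.
    """
    seed = spec.seed if seed is None else seed
    n = spec.n_haplotypes if n is None else n
    rng = np.random.default_rng(seed)
    cen, tel = _draw_motifs(spec, n, rng)
    X = _alleles_for(spec, cen, tel, rng)
    # diploid-style ids so haps/sample round trips preserve them
    hap_ids = [f"{id_prefix}{i // 2:05d}_{1 + i % 2}" for i in range(n)]
    hap_panel = HaplotypePanel(snps=_make_snp_defs(spec), haplotype_ids=hap_ids, alleles=X)
    kir = _truth_table(spec, hap_ids, cen, tel)
    truth = SyntheticTruth(haplotype_ids=hap_ids, cen_motif=list(cen),
                           tel_motif=list(tel), kir_types=kir)
    return ReferencePanel(haplotypes=hap_panel, kir_types=kir), truth, spec.copy_map()


@dataclass
class SyntheticFamilyData:
    """Simulated families: haplotypes, types, pedigree, and founder truth."""

    haplotypes: HaplotypePanel          # all members' haplotypes (complete data)
    kir_types: KirTypeTable             # haplotype-level types for all members
    pedigree: pd.DataFrame              # family_id, person_id, father_id, mother_id
    has_kir: dict[str, bool]            # per person
    has_snp: dict[str, bool]
    founder_hap_ids: list[str]          # ids of the parental haplotypes (truth)


def simulate_families(
    spec: SyntheticSpec,
    n_families: int,
    n_children: int = 2,
    missing_kir_rate: float = 0.0,
    missing_snp_rate: float = 0.0,
    seed: int | None = None,
) -> SyntheticFamilyData:
    """Simulate nuclear families: founder haplotypes drawn from the spec,
    children inheriting one haplotype per parent uniformly (no recombination
    within the region).  Per-member data availability is thinned at the given
    missingness rates to emulate partial KIR/SNP overlap in real cohorts.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_founder_haps = 4 * n_families
    cen, tel = _draw_motifs(spec, n_founder_haps, rng)
    Xf = _alleles_for(spec, cen, tel, rng)

    rows, ids, ped_rows = [], [], []
    cen_all, tel_all = [], []
    founder_ids = []
    has_kir: dict[str, bool] = {}
    has_snp: dict[str, bool] = {}
    for f in range(n_families):
        fam = f"fam{f:04d}"
        father, mother = f"{fam}_fa", f"{fam}_mo"
        ped_rows.append({"family_id": fam, "person_id": father,
                         "father_id": "0", "mother_id": "0"})
        ped_rows.append({"family_id": fam, "person_id": mother,
                         "father_id": "0", "mother_id": "0"})
        fa_idx = [4 * f, 4 * f + 1]
        mo_idx = [4 * f + 2, 4 * f + 3]
        for role, pid, hap_idx in (("fa", father, fa_idx), ("mo", mother, mo_idx)):
            for k, hi in enumerate(hap_idx, start=1):
                hid = f"{pid}_{k}"
                ids.append(hid)
                rows.append(Xf[hi])
                cen_all.append(cen[hi])
                tel_all.append(tel[hi])
            founder_ids.extend([f"{pid}_1", f"{pid}_2"])
            has_kir[pid] = rng.random() >= missing_kir_rate
            has_snp[pid] = rng.random() >= missing_snp_rate
        for c in range(n_children):
            child = f"{fam}_ch{c}"
            ped_rows.append({"family_id": fam, "person_id": child,
                             "father_id": father, "mother_id": mother})
            pat = fa_idx[int(rng.integers(2))]
            mat = mo_idx[int(rng.integers(2))]
            for k, hi in ((1, pat), (2, mat)):
                hid = f"{child}_{k}"
                ids.append(hid)
                rows.append(Xf[hi])
                cen_all.append(cen[hi])
                tel_all.append(tel[hi])
            has_kir[child] = rng.random() >= missing_kir_rate
            has_snp[child] = rng.random() >= missing_snp_rate

    panel = HaplotypePanel(snps=_make_snp_defs(spec), haplotype_ids=ids,
                           alleles=np.vstack(rows))
    kir = _truth_table(spec, ids, np.array(cen_all), np.array(tel_all))
    return SyntheticFamilyData(
        haplotypes=panel,
        kir_types=kir,
        pedigree=pd.DataFrame(ped_rows),
        has_kir=has_kir,
        has_snp=has_snp,
        founder_hap_ids=founder_ids,
    )


def simulate_validation_cohort(
    spec: SyntheticSpec, n_individuals: int, seed: int | None = None,
) -> tuple[HaplotypePanel, KirTypeTable, SyntheticTruth]:
    """Simulate an unrelated validation cohort with unphased KIR totals.

    Returns the phased haplotype panel (2n haplotypes), a per-individual
    copy-number table (totals only — no whole-haplotype classifications, as
    those are undefined without phased KIR types), and the hidden
    per-haplotype truth.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_haps = 2 * n_individuals
    cen, tel = _draw_motifs(spec, n_haps, rng)
    X = _alleles_for(spec, cen, tel, rng)
    ind_ids = [f"ind{i:05d}" for i in range(n_individuals)]
    hap_ids = [f"{iid}_{k}" for iid in ind_ids for k in (1, 2)]
    panel = HaplotypePanel(snps=_make_snp_defs(spec), haplotype_ids=hap_ids, alleles=X)
    hap_truth = _truth_table(spec, hap_ids, cen, tel)
    copies = hap_truth.values[list(COPY_NUMBER_LOCI)].astype(int).to_numpy()
    totals = copies[0::2] + copies[1::2]
    table = KirTypeTable(
        unit="individual",
        values=pd.DataFrame(totals, index=pd.Index(ind_ids),
                            columns=list(COPY_NUMBER_LOCI)).astype("Int64"),
    )
    truth = SyntheticTruth(haplotype_ids=hap_ids, cen_motif=list(cen),
                           tel_motif=list(tel), kir_types=hap_truth)
    return panel, table, truth
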