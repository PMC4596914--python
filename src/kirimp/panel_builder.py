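"""Construct an unrelated-haplotype reference panel from family data.

Family cohorts yield phased haplotypes that are identical by descent across
relatives.  Building a training panel requires (1) assigning each offspring
haplotype a parent of origin — independently from KIR types (exact vector
match) and from SNP haplotypes (Hamming distance strictly below a mismatch
budget) — (2) merging the two lines of evidence, excluding anything
ambiguous, and (3) pruning to unrelated haplotypes per family: with both
parents typed only parental haplotypes are kept; with one parent typed, that
parent's haplotypes plus any distinct offspring haplotype not carried by the
typed parent; with no parents, deduplicated offspring haplotypes.

Also provides the random pairing of panel haplotypes into pseudo-individuals
used when emulating unphased-input methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    HaplotypePanel,
    KirTypeTable,
    PanelValidationError,
    ReferencePanel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyRecord",
    "Origin",
    "Evidence",
    "OriginAssignment",
    "match_by_kir",
    "match_by_snp",
    "merge_assignments",
    "select_unrelated",
    "build_reference_panel",
    "pair_into_pseudo_individuals",
    "read_pedigree",
]

DEFAULT_MAX_MISMATCH = 20


class Origin(str, Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


class Evidence(str, Enum):
    KIR = "kir"
    SNP = "snp"
    BOTH = "both"
    CONFLICT = "conflict"
    NONE = "none"


@dataclass
class OriginAssignment:
    haplotype_id: str
    origin: Origin
    evidence: Evidence
    within_parent_ambiguous: bool = False


@dataclass
class FamilyRecord:
    """One nuclear family with per-member data availability."""

    family_id: str
    father_id: str | None
    mother_id: str | None
    child_ids: list[str]
    has_kir: dict[str, bool] = field(default_factory=dict)
    has_snp: dict[str, bool] = field(default_factory=dict)

    def members(self) -> list[str]:
        out = [p for p in (self.father_id, self.mother_id) if p]
        return out + list(self.child_ids)


def _match_one(child_vec, parent_vecs: Mapping[str, list], comparator) -> tuple[Origin, bool]:
    """Shared assignment logic: which parent's haplotypes match the child's."""
    hits = {role: [comparator(child_vec, v) for v in vecs]
            for role, vecs in parent_vecs.items()}
    matched = {role for role, flags in hits.items() if any(flags)}
    if not matched:
        return Origin.UNASSIGNED, False
    if len(matched) == 2:
        return Origin.AMBIGUOUS, False
    role = matched.pop()
    within_amb = sum(hits[role]) > 1
    origin = Origin.PATERNAL if role == "father" else Origin.MATERNAL
    return origin, within_amb


def match_by_kir(
    haplotype_id: str,
    child_types: pd.Series,
    parent_types: Mapping[str, Sequence[pd.Series]],
) -> OriginAssignment:
    """Assign parent of origin by exact match of the full KIR type vector."""
    loci = list(child_types.index)
    for role, vecs in parent_types.items():
        for v in vecs:
            if list(v.index) != loci:
                raise PanelValidationError(
                    f"{haplotype_id}: locus sets differ between child and {role}"
                )

    def exact(a: pd.Series, b: pd.Series) -> bool:
        return bool(a.eq(b).all())

    origin, within = _match_one(child_types, parent_types, exact)
    ev = Evidence.KIR if origin in (Origin.PATERNAL, Origin.MATERNAL, Origin.AMBIGUOUS) \
        else Evidence.NONE
    return OriginAssignment(haplotype_id, origin, ev, within)


def match_by_snp(
    haplotype_id: str,
    child_hap: np.ndarray,
    parent_haps: Mapping[str, Sequence[np.ndarray]],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> OriginAssignment:
    """Assign parent of origin by SNP haplotype Hamming distance.

    A parental haplotype matches iff its Hamming distance to the child's is
    strictly below ``max_mismatch`` (the default budget of 20 tolerates
    residual phasing/genotyping error over the region's SNPs).
    """
    child_hap = np.asarray(child_hap)
    for role, vecs in parent_haps.items():
        for v in vecs:
            if np.asarray(v).shape != child_hap.shape:
                raise PanelValidationError(
                    f"{haplotype_id}: SNP vector length differs from {role}"
                )

    def close(a, b) -> bool:
        return int(np.sum(np.asarray(a) != np.asarray(b))) < max_mismatch

    origin, within = _match_one(child_hap, parent_haps, close)
    ev = Evidence.SNP if origin in (Origin.PATERNAL, Origin.MATERNAL, Origin.AMBIGUOUS) \
        else Evidence.NONE
    return OriginAssignment(haplotype_id, origin, ev, within)


def merge_assignments(kir: OriginAssignment, snp: OriginAssignment) -> OriginAssignment:
    """Merge KIR- and SNP-based assignments; anything ambiguous is excluded.

    Agreement keeps the origin with evidence 'both'; a single line of
    evidence stands alone; disagreement or ambiguity on either side marks the
    haplotype ambiguous with evidence 'conflict' (to be excluded).
    """
    if kir.haplotype_id != snp.haplotype_id:
        raise ValueError("assignments refer to different haplotypes")
    hid = kir.haplotype_id
    sides = {Origin.PATERNAL, Origin.MATERNAL}
    if kir.origin == Origin.AMBIGUOUS or snp.origin == Origin.AMBIGUOUS:
        return OriginAssignment(hid, Origin.AMBIGUOUS, Evidence.CONFLICT)
    if kir.origin in sides and snp.origin in sides:
        if kir.origin == snp.origin:
            return OriginAssignment(hid, kir.origin, Evidence.BOTH,
                                    kir.within_parent_ambiguous or snp.within_parent_ambiguous)
        return OriginAssignment(hid, Origin.AMBIGUOUS, Evidence.CONFLICT)
    if kir.origin in sides:
        return OriginAssignment(hid, kir.origin, Evidence.KIR, kir.within_parent_ambiguous)
    if snp.origin in sides:
        return OriginAssignment(hid, snp.origin, Evidence.SNP, snp.within_parent_ambiguous)
    return OriginAssignment(hid, Origin.UNASSIGNED, Evidence.NONE)


# ---------------------------------------------------------------------------


def _hap_ids(person: str) -> list[str]:
    return [f"{person}_1", f"{person}_2"]


class _HapData:
    """Lookup of SNP vectors and KIR type vectors by haplotype id."""

    def __init__(self, panel: HaplotypePanel | None, kir: KirTypeTable | None):
        self._snp_index = {h: i for i, h in enumerate(panel.haplotype_ids)} if panel else {}
        self._panel = panel
        self._kir = kir

    def snp(self, hid: str) -> np.ndarray | None:
        i = self._snp_index.get(hid)
        return None if i is None else self._panel.alleles[i]

    def kir(self, hid: str) -> pd.Series | None:
        if self._kir is None or hid not in self._kir.values.index:
            return None
        return self._kir.values.loc[hid]


def _assign_child_hap(hid: str, data: _HapData, family: FamilyRecord,
                      person_of, max_mismatch: int) -> OriginAssignment:
    parent_kir = {}
    parent_snp = {}
    for role, pid in (("father", family.father_id), ("mother", family.mother_id)):
        if pid is None:
            continue
        if family.has_kir.get(pid, False):
            vecs = [data.kir(h) for h in _hap_ids(pid)]
            vecs = [v for v in vecs if v is not None]
            if vecs:
                parent_kir[role] = vecs
        if family.has_snp.get(pid, False):
            vecs = [data.snp(h) for h in _hap_ids(pid)]
            vecs = [v for v in vecs if v is not None]
            if vecs:
                parent_snp[role] = vecs
    person = person_of(hid)
    kir_a = OriginAssignment(hid, Origin.UNASSIGNED, Evidence.NONE)
    snp_a = OriginAssignment(hid, Origin.UNASSIGNED, Evidence.NONE)
    if parent_kir and family.has_kir.get(person, False) and data.kir(hid) is not None:
        kir_a = match_by_kir(hid, data.kir(hid), parent_kir)
    if parent_snp and family.has_snp.get(person, False) and data.snp(hid) is not None:
        snp_a = match_by_snp(hid, data.snp(hid), parent_snp, max_mismatch)
    return merge_assignments(kir_a, snp_a)


def select_unrelated(
    family: FamilyRecord,
    data: _HapData,
    assignments: Mapping[str, OriginAssignment],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[str]:
    """Choose the unrelated haplotypes a family contributes to the panel."""
    typed = lambda p: p is not None and (family.has_kir.get(p, False)
                                         or family.has_snp.get(p, False))
    typed_parents = [p for p in (family.father_id, family.mother_id) if typed(p)]
    if len(typed_parents) == 2:
        return [h for p in typed_parents for h in _hap_ids(p)]

    def same_hap(h1: str, h2: str) -> bool:
        k1, k2 = data.kir(h1), data.kir(h2)
        s1, s2 = data.snp(h1), data.snp(h2)
        kir_eq = k1 is not None and k2 is not None and bool(k1.eq(k2).all())
        snp_eq = s1 is not None and s2 is not None and np.array_equal(s1, s2)
        if k1 is not None and k2 is not None and not kir_eq:
            return False
        if s1 is not None and s2 is not None and not snp_eq:
            return False
        return kir_eq or snp_eq

    child_haps = [h for c in family.child_ids for h in _hap_ids(c)
                  if data.snp(h) is not None or data.kir(h) is not None]

    if len(typed_parents) == 1:
        parent = typed_parents[0]
        kept = _hap_ids(parent)
        candidates = []
        for h in child_haps:
            a = assignments.get(h)
            if a is not None and a.origin == Origin.AMBIGUOUS:
                continue
            # keep only haplotypes not present in the typed parent
            if any(_matches_parent(data, h, ph, max_mismatch) for ph in _hap_ids(parent)):
                continue
            candidates.append(h)
        return kept + _dedup(candidates, same_hap)

    return _dedup(child_haps, same_hap)


def _matches_parent(data: _HapData, child_h: str, parent_h: str, max_mismatch: int) -> bool:
    ck, pk = data.kir(child_h), data.kir(parent_h)
    cs, ps = data.snp(child_h), data.snp(parent_h)
    if ck is not None and pk is not None and bool(ck.eq(pk).all()):
        return True
    if cs is not None and ps is not None and \
            int(np.sum(cs != ps)) < max_mismatch:
        return True
    return False


def _dedup(haps: list[str], same) -> list[str]:
    kept: list[str] = []
    for h in haps:
        if not any(same(h, k) for k in kept):
            kept.append(h)
    return kept


def build_reference_panel(
    families: Sequence[FamilyRecord],
    snp_panel: HaplotypePanel,
    kir_table: KirTypeTable,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[ReferencePanel, pd.DataFrame]:
    """Assemble the unrelated reference panel and an exclusion log.

    Haplotypes with either SNP or KIR data missing participate in matching
    but are excluded from the final panel, which requires complete rows.
    """
    data = _HapData(snp_panel, kir_table)
    person_of = lambda hid: hid.rsplit("_", 1)[0]
    selected: list[str] = []
    log_rows = []
    for family in families:
        assignments: dict[str, OriginAssignment] = {}
        for child in family.child_ids:
            for hid in _hap_ids(child):
                if data.snp(hid) is None and data.kir(hid) is None:
                    continue
                a = _assign_child_hap(hid, data, family, person_of, max_mismatch)
                assignments[hid] = a
                if a.origin == Origin.AMBIGUOUS:
                    log_rows.append({"family_id": family.family_id, "haplotype_id": hid,
                                     "step": "origin_merge", "reason": "ambiguous"})
        chosen = select_unrelated(family, data, assignments, max_mismatch)
        for hid in chosen:
            person = person_of(hid)
            if not (family.has_snp.get(person, False) and family.has_kir.get(person, False)):
                log_rows.append({"family_id": family.family_id, "haplotype_id": hid,
                                 "step": "completeness",
                                 "reason": "missing SNP or KIR data"})
                continue
            if data.snp(hid) is None or data.kir(hid) is None:
                log_rows.append({"family_id": family.family_id, "haplotype_id": hid,
                                 "step": "completeness", "reason": "data not found"})
                continue
            selected.append(hid)
    if not selected:
        raise PanelValidationError("no haplotypes survive panel construction")
    index = {h: i for i, h in enumerate(snp_panel.haplotype_ids)}
    rows = [index[h] for h in selected]
    panel = ReferencePanel(
        haplotypes=snp_panel.subset_haplotypes(rows),
        kir_types=KirTypeTable(unit="haplotype", values=kir_table.values.loc[selected]),
    )
    log = pd.DataFrame(log_rows, columns=["family_id", "haplotype_id", "step", "reason"])
    return panel, log


def pair_into_pseudo_individuals(
    haplotype_ids: Sequence[str], seed: int = 0
) -> list[tuple[str, str]]:
    """Randomly pair haplotypes (without replacement) into pseudo-individuals.

    With an odd count, the haplotype left after the seeded shuffle is
    discarded.  Deterministic given the seed.
    """
    ids = list(haplotype_ids)
    if len(ids) < 2:
        raise ValueError("need at least two haplotypes to pair")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    return [(ids[perm[2 * i]], ids[perm[2 * i + 1]]) for i in range(half)]


def read_pedigree(path, sep: str = "\t") -> list[FamilyRecord]:
    """Read a pedigree TSV (family_id, person_id, father_id, mother_id).

    '0' or empty parent ids mean founder.  Optional has_kir/has_snp columns
    (0/1) mark data availability; absent columns default to available.
    """
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("0")
    families: dict[str, FamilyRecord] = {}
    for fam_id, grp in df.groupby("family_id", sort=False):
        father = mother = None
        children = []
        has_kir: dict[str, bool] = {}
        has_snp: dict[str, bool] = {}
        parents = set(grp["father_id"]) | set(grp["mother_id"])
        for _, row in grp.iterrows():
            pid = row["person_id"]
            has_kir[pid] = row.get("has_kir", "1") not in ("0", "")
            has_snp[pid] = row.get("has_snp", "1") not in ("0", "")
            if row["father_id"] in ("0", "") and row["mother_id"] in ("0", ""):
                if pid in set(grp["father_id"]):
                    father = pid
                elif pid in set(grp["mother_id"]):
                    mother = pid
                elif pid not in parents:
                    children.append(pid)  # unconnected member; treated as offspring
            else:
                children.append(pid)
        families[fam_id] = FamilyRecord(
            family_id=fam_id, father_id=father, mother_id=mother,
            child_ids=children, has_kir=has_kir, has_snp=has_snp,
        )
    return list(families.values())
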