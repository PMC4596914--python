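"""kirimp: imputation of KIR gene copy number from phased SNP haplotypes.

Per-locus random-forest classifiers trained on a reference panel of phased
haplotypes with known KIR types, plus the surrounding machinery: panel
construction from families, allele alignment between panels, cross-validation
and calibration assessment, informative-SNP selection, and a synthetic
KIR-region simulator with known truth.
"""

from importlib import resources

import pandas as pd

from .forest import Forest, ForestParams, default_m_try, fit_forest, sqrt_m_try
from .imputation import (
    CallPolicy,
    ImputationResult,
    KirImputationModel,
    KirImputationResults,
    apply_threshold,
    coarsen,
    fit_locus_models,
    impute_individuals,
)
from .panel_io import (
    ALL_LOCI,
    AVSB_LOCUS,
    COPY_NUMBER_LOCI,
    HAPLOTYPE_LOCUS,
    HaplotypePanel,
    KirTypeTable,
    ReferencePanel,
    SnpDefinition,
    align_alleles,
    drop_monomorphic,
    filter_by_region,
    read_haps,
    read_kir_types,
    read_vcf_phased,
    write_haps,
    write_vcf_phased,
)
from .synthetic import SyntheticSpec, default_spec, long_tail_spec, simulate_panel

__version__ = "0.1.0"


def load_informative_snps() -> pd.DataFrame:
    """The published table of most-informative KIR-imputation SNPs.

    16 Immunochip SNPs with GRCh37 positions, alleles, gene annotation and
    the poor-clustering QC flag; dropping the poor-clustering SNPs yields the
    12-SNP selected set.
    """
    with resources.files("kirimp").joinpath("data/informative_snps.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["poor_clustering"] = df["poor_clustering"].eq("yes")
    df["in_validation_panel"] = df["in_validation_panel"].eq("yes")
    return df
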