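"""B-cell receptor (IGH) repertoire analysis.

Clone-collapsed repertoire measures (isotype expression/usage, SHM-gated
class switching, V-allele usage, per-isotype CDR3 length, Hill diversity
profiles), a cohort measure-prevalence filter, multivariable
exposure-association models with Benjamini-Hochberg FDR tiers, and a
seeded synthetic cohort generator.
"""

__version__ = "0.1.0"

from .association import (
    FAMILIES,
    bh_adjust,
    build_design,
    fit_linear,
    run_analysis,
    tier_of,
    write_results,
)
from .clones import (
    assign_clones,
    collapse_clones,
    group_clones,
    write_clone_table,
)
from .errors import (
    ConfigError,
    ContractError,
    DataError,
    EmptyRepertoireError,
    IghrepError,
    ModelError,
    RowValidationError,
    SchemaError,
    UnknownIsotypeError,
)
from .io import (
    CLASS_SWITCHED,
    ISOTYPES,
    is_class_switched,
    map_isotype,
    read_metadata,
    read_rearrangements,
    write_metadata,
    write_rearrangements,
)
from .measures import (
    DEFAULT_Q_GRID,
    HillProfile,
    cdr3_length_by_isotype,
    class_switching_proportion,
    hill_profile,
    isotype_measures,
    prevalence_filter,
    summarize_cohort,
    summarize_repertoire,
    v_allele_measures,
)
from .simulate import (
    CohortConfig,
    CovariateConfig,
    GroupEffectConfig,
    default_cohort_config,
    default_group_effects,
    load_cohort_config,
    save_cohort_config,
    simulate_cohort,
    simulate_repertoire,
)
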