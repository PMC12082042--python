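"""Per-participant repertoire measures and the cohort prevalence filter.

All measures are computed on clone-collapsed units (one record per
participant × clone × isotype subclass, ``N`` units in total per
participant):

* isotype count ``n_c``, usage ``u_c = n_c / N``, and expression
  ``e_c = log2(n_c + 1)`` (the pseudo-count keeps the log defined at 0);
* class switching ``s`` — the proportion of units that belong to a
  switched subclass (IgA/IgG/IgE) *and* carry somatic hypermutation
  (mutation gate applied at clone collapse);
* V-allele usage — mutated units carrying the allele over ``N`` — and
  per-allele class switching (mutated, switched units over ``N``);
* mean CDR3 (junction) length in nucleotides per subclass, missing when a
  subclass has no units;
* a Hill diversity profile ``D_q`` over a grid of orders ``q``, computed
  on clone read abundances (isotypes within a clone merged, since
  diversity measures clonal expansion, not class composition):
  ``D_q = (sum_i p_i^q)^(1/(1-q))`` with the Shannon limit
  ``D_1 = exp(-sum_i p_i ln p_i)``.

A measure-prevalence filter keeps only isotype / V-allele categories whose
usage exceeds ``min_usage`` (default 1%) in at least
``ceil(min_participant_fraction * n)`` participants (default 25%), with IgE
retained unconditionally for its clinical importance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyRepertoireError
from .io import CLASS_SWITCHED, ISOTYPES

log = logging.getLogger("ighrep")

#: Diversity orders used by default: q from 0 to 4 in steps of 0.1.
DEFAULT_Q_GRID = np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 10)

#: Orders whose log-Hill values enter the per-participant measure matrix.
MATRIX_Q = (0.0, 1.0, 2.0)

DEFAULT_MIN_USAGE = 0.01
DEFAULT_MIN_PARTICIPANT_FRACTION = 0.25
ALWAYS_KEEP_ISOTYPES = frozenset({"IgE"})


# --- single-repertoire measures -----------------------------------------


def _require_nonempty(clones: pd.DataFrame) -> int:
    n = len(clones)
    if n == 0:
        raise EmptyRepertoireError("participant has no clone records")
    return n


def isotype_measures(
    clones: pd.DataFrame, pseudocount: float = 1.0
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """(count, usage, expression) per isotype subclass for one participant."""
    n_total = _require_nonempty(clones)
    counts = clones["isotype"].value_counts().reindex(ISOTYPES, fill_value=0)
    counts.name = "isotype_count"
    usage = (counts / n_total).rename("isotype_usage")
    expression = np.log2(counts + pseudocount).rename("isotype_expression")
    return counts, usage, expression


def class_switching_proportion(clones: pd.DataFrame) -> float:
    """Fraction of units that are class-switched AND somatically mutated."""
    n_total = _require_nonempty(clones)
    switched = clones["isotype"].isin(CLASS_SWITCHED) & clones["mutated"]
    return float(switched.sum()) / n_total


def v_allele_measures(clones: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(usage, class_switching) per V allele for one participant.

    Both numerators count only mutated units (unmutated sequences carry no
    evidence that the allele was engaged by an immune response); the
    denominator is all ``N`` units, so totals may sum to less than 1.
    """
    n_total = _require_nonempty(clones)
    mutated = clones[clones["mutated"]]
    usage = mutated.groupby("v_allele").size().sort_index() / n_total
    switched = mutated[mutated["isotype"].isin(CLASS_SWITCHED)]
    switching = (
        switched.groupby("v_allele").size().reindex(usage.index, fill_value=0)
        / n_total
    )
    return usage.rename("v_allele_usage"), switching.rename("v_allele_class_switching")


def cdr3_length_by_isotype(clones: pd.DataFrame, stat: str = "mean") -> pd.Series:
    """Mean (or median) junction length in nucleotides per subclass.

    Subclasses with no units are NaN (missing, not zero).
    """
    if stat not in ("mean", "median"):
        raise ContractError(f"cdr3 statistic must be mean or median, got {stat!r}")
    if clones.empty:
        return pd.Series(np.nan, index=list(ISOTYPES), name="cdr3_length")
    agg = clones.groupby("isotype")["junction_length"].agg(stat)
    return agg.reindex(ISOTYPES).astype(float).rename("cdr3_length")


@dataclass(frozen=True)
class HillProfile:
    """Hill diversity numbers D_q over a grid of orders q.

    D_0 is clone richness; D_1 the exponential of Shannon entropy; D_2 the
    inverse Simpson index. D_q is non-increasing in q, and lower values at
    q > 0 indicate clonal expansion.
    """

    q_grid: np.ndarray
    values: np.ndarray
    log_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.log_values is None:
            object.__setattr__(self, "log_values", np.log(self.values))


def hill_profile(abundances, q_grid=DEFAULT_Q_GRID) -> HillProfile:
    """Hill numbers of a clone abundance vector over a grid of orders.

    ``D_q = (sum_i p_i^q)^(1/(1-q))`` for q != 1 and
    ``D_1 = exp(-sum_i p_i ln p_i)``, with ``p_i`` the clone relative
    abundances. All abundances must be >= 1 (positive integers).
    """
    a = np.asarray(abundances, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if a.size == 0:
        raise ContractError("empty abundance vector")
    if (a < 1).any():
        raise ContractError("abundances must all be >= 1")
    if (q < 0).any():
        raise ContractError("diversity orders q must be >= 0")
    p = a / a.sum()
    log_d = np.empty_like(q)
    is_one = q == 1.0
    is_zero = q == 0.0  # special-cased so D_0 is exactly the richness
    if is_one.any():
        log_d[is_one] = -(p * np.log(p)).sum()
    if is_zero.any():
        log_d[is_zero] = np.log(p.size)
    rest = ~(is_one | is_zero)
    qn = q[rest]
    if qn.size:
        sums = np.power(p[:, None], qn[None, :]).sum(axis=0)
        log_d[rest] = np.log(sums) / (1.0 - qn)
    values = np.exp(log_d)
    values[is_zero] = float(p.size)
    return HillProfile(q_grid=q, values=values, log_values=log_d)


def summarize_repertoire(
    clones: pd.DataFrame,
    q_grid=DEFAULT_Q_GRID,
    cdr3_stat: str = "mean",
    pseudocount: float = 1.0,
) -> tuple[pd.Series, HillProfile]:
    """All measures for one participant's clone records.

    Returns a named Series (measure name -> value) and the full Hill
    profile; the Series carries log-Hill values at q in ``MATRIX_Q``.
    """
    _require_nonempty(clones)
    counts, usage, expression = isotype_measures(clones, pseudocount)
    s = class_switching_proportion(clones)
    v_usage, v_switch = v_allele_measures(clones)
    cdr3 = cdr3_length_by_isotype(clones, cdr3_stat)
    clone_abund = clones.groupby("clone_id")["abundance"].sum().to_numpy()
    profile = hill_profile(clone_abund, q_grid)

    out: dict[str, float] = {"total unique": float(counts.sum())}
    for iso in ISOTYPES:
        out[f"{iso} usage"] = usage[iso]
        out[f"{iso} expression"] = expression[iso]
        out[f"{iso} CDR3 length"] = cdr3[iso]
    out["class switching"] = s
    for allele, val in v_usage.items():
        out[f"{allele} usage"] = val
    for allele, val in v_switch.items():
        out[f"{allele} class switching"] = val
    for q0 in MATRIX_Q:
        idx = int(np.argmin(np.abs(np.asarray(q_grid, float) - q0)))
        out[f"log-Hill q={q0:g}"] = profile.log_values[idx]
    return pd.Series(out), profile


# --- cohort-level summary and prevalence filter -------------------------


def prevalence_filter(
    usage: pd.DataFrame,
    min_usage: float = DEFAULT_MIN_USAGE,
    min_participant_fraction: float = DEFAULT_MIN_PARTICIPANT_FRACTION,
    always_keep: frozenset = frozenset(),
) -> list[str]:
    """Categories retained by the cohort prevalence rule.

    *usage* is a participants × categories table of usage fractions. A
    category is retained iff strictly more than *min_usage* of unique
    sequences belong to it in at least
    ``ceil(min_participant_fraction * n_participants)`` participants.
    ``always_keep`` members are retained unconditionally.
    """
    n = len(usage)
    if n == 0:
        raise ContractError("prevalence filter needs at least one participant")
    needed = math.ceil(min_participant_fraction * n)
    retained = []
    for cat in usage.columns:
        if cat in always_keep or int((usage[cat] > min_usage).sum()) >= needed:
            retained.append(cat)
    return retained


def summarize_cohort(
    clone_records: pd.DataFrame,
    q_grid=DEFAULT_Q_GRID,
    cdr3_stat: str = "mean",
    pseudocount: float = 1.0,
    min_usage: float = DEFAULT_MIN_USAGE,
    min_participant_fraction: float = DEFAULT_MIN_PARTICIPANT_FRACTION,
    apply_filter: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant measure matrix for a whole cohort.

    Returns ``(matrix, manifest)``: *matrix* is participants × measures,
    *manifest* one row per measure (name, family, category). The
    prevalence filter is applied separately to the isotype and V-allele
    families; class switching and diversity are always reported.
    Implemented with vectorized cross-tabulations so large simulated
    cohorts summarize quickly.
    """
    if clone_records.empty:
        raise EmptyRepertoireError("cohort has no clone records")
    df = clone_records
    n_units = df.groupby("participant_id").size()
    participants = n_units.index

    iso_counts = (
        pd.crosstab(df["participant_id"], df["isotype"])
        .reindex(index=participants, columns=list(ISOTYPES), fill_value=0)
    )
    iso_usage = iso_counts.div(n_units, axis=0)
    iso_expr = np.log2(iso_counts + pseudocount)

    sw = df["isotype"].isin(CLASS_SWITCHED) & df["mutated"]
    switching = sw.groupby(df["participant_id"]).sum() / n_units

    mut = df[df["mutated"]]
    v_usage = (
        pd.crosstab(mut["participant_id"], mut["v_allele"])
        .reindex(index=participants, fill_value=0)
        .div(n_units, axis=0)
    )
    mut_sw = mut[mut["isotype"].isin(CLASS_SWITCHED)]
    v_switch = (
        pd.crosstab(mut_sw["participant_id"], mut_sw["v_allele"])
        .reindex(index=participants, columns=v_usage.columns, fill_value=0)
        .div(n_units, axis=0)
    )

    cdr3 = df.pivot_table(
        index="participant_id", columns="isotype", values="junction_length",
        aggfunc=cdr3_stat,
    ).reindex(index=participants, columns=list(ISOTYPES))

    clone_abund = df.groupby(["participant_id", "clone_id"])["abundance"].sum()
    q = np.asarray(q_grid, dtype=float)
    q_cols = {q0: int(np.argmin(np.abs(q - q0))) for q0 in MATRIX_Q}
    hill_rows = {}
    for pid, vec in clone_abund.groupby(level=0):
        prof = hill_profile(vec.to_numpy(), q)
        hill_rows[pid] = [prof.log_values[i] for i in q_cols.values()]
    hill = pd.DataFrame.from_dict(
        hill_rows, orient="index",
        columns=[f"log-Hill q={q0:g}" for q0 in MATRIX_Q],
    ).reindex(participants)

    if apply_filter:
        keep_iso = prevalence_filter(
            iso_usage, min_usage, min_participant_fraction, ALWAYS_KEEP_ISOTYPES
        )
        keep_allele = prevalence_filter(
            v_usage, min_usage, min_participant_fraction
        )
        dropped_iso = [c for c in iso_usage.columns if c not in keep_iso]
        dropped_allele = [c for c in v_usage.columns if c not in keep_allele]
        log.info(
            "prevalence filter: retained %d/%d isotypes (dropped: %s), "
            "%d/%d V alleles (dropped: %s)",
            len(keep_iso), iso_usage.shape[1], dropped_iso or "none",
            len(keep_allele), v_usage.shape[1], dropped_allele or "none",
        )
    else:
        keep_iso = list(iso_usage.columns)
        keep_allele = list(v_usage.columns)

    manifest_rows = []
    matrix = pd.DataFrame(index=participants)
    matrix["total unique"] = n_units.astype(float)
    manifest_rows.append(("total unique", "totals", ""))
    for iso in keep_iso:
        matrix[f"{iso} usage"] = iso_usage[iso]
        manifest_rows.append((f"{iso} usage", "isotype_usage", iso))
    for iso in keep_iso:
        matrix[f"{iso} expression"] = iso_expr[iso]
        manifest_rows.append((f"{iso} expression", "isotype_expression", iso))
    matrix["class switching"] = switching
    manifest_rows.append(("class switching", "class_switching", ""))
    for allele in keep_allele:
        matrix[f"{allele} usage"] = v_usage[allele]
        manifest_rows.append((f"{allele} usage", "v_allele_usage", allele))
    for allele in keep_allele:
        matrix[f"{allele} class switching"] = v_switch[allele]
        manifest_rows.append(
            (f"{allele} class switching", "v_allele_class_switching", allele)
        )
    for iso in keep_iso:
        matrix[f"{iso} CDR3 length"] = cdr3[iso]
        manifest_rows.append((f"{iso} CDR3 length", "cdr3_length", iso))
    for col in hill.columns:
        matrix[col] = hill[col]
        manifest_rows.append((col, "diversity", col.split("=")[1]))

    manifest = pd.DataFrame(manifest_rows, columns=["measure", "family", "category"])
    matrix.index.name = "participant_id"
    return matrix, manifest


def write_measure_matrix(matrix: pd.DataFrame, manifest: pd.DataFrame, path) -> None:
    """Write the measure matrix CSV plus its column manifest alongside."""
    matrix.to_csv(path)
    manifest.to_csv(str(path) + ".manifest.csv", index=False)


def read_measure_matrix(path) -> pd.DataFrame:
    """Read a measure matrix CSV written by :func:`write_measure_matrix`."""
    return pd.read_csv(path, index_col="participant_id")
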