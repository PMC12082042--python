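"""Multivariable exposure-association models with BH-FDR tiers.

Every retained repertoire measure is regressed (ordinary least squares, on
its native scale) on a family-specific covariate set. Exposure group is
dummy-coded with *former smokers* as the reference; GOLD spirometry group
with *normal spirometry* as the reference. Benjamini–Hochberg FDR
adjustment is applied within each analysis family across all
(measure × term-of-interest) p-values jointly, and results are tiered:
significant (q < 0.05), suggestive (0.05 <= q < 0.1), null otherwise.

Families
--------
primary
    age + sex + race + exposure group + GOLD group + pack-years + inhaled
    corticosteroid use; reported terms: age, sex, race, exposure and GOLD
    contrasts.
sensitivity_ses
    primary covariates plus income level and area deprivation index;
    reported terms: exposure contrasts and race.
sensitivity_pcs
    primary covariates plus genetic principal components (columns
    ``pc1``, ``pc2``, ...); reported terms: exposure contrasts and race.
interaction
    primary covariates plus race × exposure cross-products; reported
    terms: the cross-products.
univariable_copd
    GOLD group + inhaled corticosteroid use only; reported terms: GOLD
    contrasts.
univariable_ct
    CT airway wall area % + CT scanner model + inhaled corticosteroid use;
    reported term: wall area %.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, ContractError, DataError, ModelError
from .io import EXPOSURE_LEVELS, GOLD_LEVELS

log = logging.getLogger("ighrep")

SIGNIFICANT_Q = 0.05
SUGGESTIVE_Q = 0.10

#: Reference levels for categorical covariates.
REFERENCES = {"exposure_group": "former", "gold_group": "normal"}

#: Canonical dummy order for known categoricals (reference listed first is
#: irrelevant; the reference is dropped).
LEVEL_ORDER = {"exposure_group": EXPOSURE_LEVELS, "gold_group": GOLD_LEVELS}

_CATEGORICAL = {"exposure_group", "gold_group", "ct_scanner"}


@dataclass(frozen=True)
class FamilySpec:
    """Covariate set and reported terms for one analysis family."""

    terms: tuple[str, ...]
    interest: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = field(default=())


_PRIMARY_TERMS = (
    "age", "sex", "race", "exposure_group", "gold_group", "pack_years", "ics_use",
)

FAMILIES: dict[str, FamilySpec] = {
    "primary": FamilySpec(
        _PRIMARY_TERMS, ("age", "sex", "race", "exposure_group", "gold_group")
    ),
    "sensitivity_ses": FamilySpec(
        _PRIMARY_TERMS + ("income_level", "deprivation_index"),
        ("exposure_group", "race"),
    ),
    "sensitivity_pcs": FamilySpec(
        _PRIMARY_TERMS + ("genetic_pcs",), ("exposure_group", "race")
    ),
    "interaction": FamilySpec(
        _PRIMARY_TERMS, ("race*exposure_group",),
        interactions=(("race", "exposure_group"),),
    ),
    "univariable_copd": FamilySpec(("gold_group", "ics_use"), ("gold_group",)),
    "univariable_ct": FamilySpec(
        ("ct_wall_area_pct", "ct_scanner", "ics_use"), ("ct_wall_area_pct",)
    ),
}


# --- design matrices ----------------------------------------------------


def _expand_terms(metadata: pd.DataFrame, terms) -> list[str]:
    """Resolve pseudo-terms (genetic_pcs) to concrete metadata columns."""
    cols = []
    for t in terms:
        if t == "genetic_pcs":
            pcs = sorted(
                (c for c in metadata.columns if re.fullmatch(r"pc\d+", c)),
                key=lambda c: int(c[2:]),
            )
            if not pcs:
                raise ModelError("genetic_pcs requested but no pc columns in metadata")
            cols.extend(pcs)
        else:
            cols.append(t)
    return cols


def build_design(
    metadata: pd.DataFrame,
    terms,
    interactions: tuple[tuple[str, str], ...] = (),
) -> pd.DataFrame:
    """Design matrix (intercept first) from participant metadata.

    Categorical covariates are dummy-coded against their reference level
    with deterministic column order and names ``"<var>:<level>"``;
    interaction columns are named ``"<var1>*<var2>:<level>"``. Rows with
    missing values in any used covariate are dropped (and the drop count
    logged). Raises :class:`~ighrep.errors.ModelError` when a reference
    level is absent or the matrix is rank-deficient.
    """
    cols = _expand_terms(metadata, terms)
    missing_cols = [c for c in cols if c not in metadata.columns]
    if missing_cols:
        raise ModelError(f"metadata lacks covariate(s): {', '.join(missing_cols)}")
    sub = metadata.set_index("participant_id")[cols] if "participant_id" in metadata \
        else metadata[cols]
    n_before = len(sub)
    sub = sub.dropna()
    if n_before - len(sub):
        log.info("complete-case analysis: dropped %d/%d rows with missing covariates",
                 n_before - len(sub), n_before)

    X = pd.DataFrame(index=sub.index)
    X["intercept"] = 1.0
    dummy_cols: dict[str, list[str]] = {}
    for var in cols:
        vals = sub[var]
        if var in _CATEGORICAL or vals.dtype == object:
            levels = [str(v) for v in pd.unique(vals.astype(str))]
            order = LEVEL_ORDER.get(var)
            if order is not None:
                levels = [l for l in order if l in levels]
            else:
                levels = sorted(levels)
            ref = REFERENCES.get(var, levels[0])
            if ref not in levels:
                raise ModelError(f"reference level {ref!r} absent from {var}")
            dummy_cols[var] = []
            for level in levels:
                if level == ref:
                    continue
                name = f"{var}:{level}"
                X[name] = (vals.astype(str) == level).astype(float)
                dummy_cols[var].append(name)
        else:
            X[var] = vals.astype(float)
            dummy_cols[var] = [var]
    for v1, v2 in interactions:
        for c1 in dummy_cols[v1]:
            for c2 in dummy_cols[v2]:
                X[f"{c1}*{c2}"] = X[c1] * X[c2]

    arr = X.to_numpy(dtype=float)
    constant = [c for c in X.columns[1:] if np.ptp(X[c].to_numpy()) == 0.0]
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        raise ModelError(
            "design matrix is rank-deficient"
            + (f" (constant column(s): {', '.join(constant)})" if constant else "")
        )
    if constant:
        log.warning("constant design column(s): %s", ", ".join(constant))
    return X


def fit_linear(X: pd.DataFrame, y) -> pd.DataFrame:
    """OLS fit; one row per design column with beta, se, and two-sided p.

    Standard errors use the residual variance with n - k degrees of
    freedom and p-values come from the t distribution.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k + 1:
        raise ModelError(f"need at least {k + 1} rows for {k} columns, have {n}")
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    return pd.DataFrame(
        {"term": list(X.columns), "beta": res.params, "se": res.bse, "p": res.pvalues}
    )


# --- multiple testing ---------------------------------------------------


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1 and mapped back to
    the input order. *m* defaults to the number of p-values but may be
    larger when the family is wider than the vector supplied.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ContractError("bh_adjust expects a non-empty 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ContractError("p-values must lie in [0, 1]")
    n = p.size
    m = n if m is None else int(m)
    if m < n:
        raise ContractError(f"family size m={m} smaller than vector length {n}")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def tier_of(q: np.ndarray) -> np.ndarray:
    """Map q-values onto significance tiers."""
    q = np.asarray(q, dtype=float)
    return np.where(q < SIGNIFICANT_Q, "significant",
                    np.where(q < SUGGESTIVE_Q, "suggestive", "null"))


# --- analysis driver ----------------------------------------------------


def _interest_columns(columns, interest) -> list[str]:
    out = []
    for col in columns:
        if col == "intercept":
            continue
        base = col.split(":")[0]
        for want in interest:
            if col == want or base == want:
                out.append(col)
                break
    return out


def run_analysis(
    measure_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    family_label: str = "primary",
    measures=None,
) -> pd.DataFrame:
    """Fit one model per measure and BH-adjust across the whole family.

    Participants flagged ``oral_steroids`` are excluded before modelling
    (oral corticosteroids modify B-cell function). The measure matrix and
    metadata must cover the same participants; an alignment mismatch is an
    error listing the unmatched ids. Returns one row per
    (measure, term-of-interest) sorted by q.
    """
    if family_label not in FAMILIES:
        raise ConfigError(
            f"unknown analysis family {family_label!r}; "
            f"known: {', '.join(sorted(FAMILIES))}"
        )
    spec = FAMILIES[family_label]

    meta = metadata.copy()
    if "oral_steroids" in meta.columns:
        n_drop = int(meta["oral_steroids"].fillna(False).astype(bool).sum())
        if n_drop:
            log.info("excluding %d participants on oral corticosteroids", n_drop)
        meta = meta[~meta["oral_steroids"].fillna(False).astype(bool)]
    meta = meta.set_index("participant_id") if "participant_id" in meta.columns else meta

    mat_ids = set(map(str, measure_matrix.index))
    meta_ids = set(map(str, meta.index))
    only_mat = sorted(mat_ids - meta_ids)
    only_meta = sorted(meta_ids - mat_ids)
    if only_mat or only_meta:
        raise DataError(
            f"participant mismatch: {len(only_mat)} only in measures "
            f"(e.g. {only_mat[:3]}), {len(only_meta)} only in metadata "
            f"(e.g. {only_meta[:3]})"
        )
    meta = meta.loc[measure_matrix.index.astype(str)]

    use_measures = list(measures) if measures is not None else [
        c for c in measure_matrix.columns if c != "total unique"
    ]
    rows = []
    skipped = []
    for measure in use_measures:
        if measure not in measure_matrix.columns:
            raise ConfigError(f"measure {measure!r} not in matrix")
        y = measure_matrix[measure].astype(float)
        y.index = y.index.astype(str)
        ok = y.notna()
        sub_meta = meta.loc[ok.to_numpy()].reset_index(names="participant_id")
        try:
            X = build_design(sub_meta, spec.terms, spec.interactions)
        except ModelError as exc:
            # a rare measure can leave a complete-case subset in which a
            # covariate is aliased or a reference level vanishes; the model
            # is not estimable there, so the measure is reported as skipped
            skipped.append(measure)
            log.warning("skipping measure %r: %s", measure, exc)
            continue
        yy = y[ok].loc[X.index].to_numpy()
        fit = fit_linear(X, yy)
        keep = _interest_columns(X.columns, spec.interest)
        fit = fit[fit["term"].isin(keep)].copy()
        fit.insert(0, "measure", measure)
        fit["n_used"] = len(X)
        rows.append(fit)

    if not rows:
        raise ModelError(
            f"no estimable model in family {family_label!r}; "
            f"skipped: {', '.join(skipped)}"
        )
    results = pd.concat(rows, ignore_index=True)
    results["q"] = bh_adjust(results["p"].to_numpy())
    results["tier"] = tier_of(results["q"].to_numpy())
    results["family"] = family_label
    results = results.sort_values(["q", "p", "measure", "term"], kind="mergesort")
    results = results.reset_index(drop=True)
    log.info(
        "family %s: %d tests, %d significant, %d suggestive",
        family_label, len(results),
        int((results["tier"] == "significant").sum()),
        int((results["tier"] == "suggestive").sum()),
    )
    return results[
        ["measure", "term", "beta", "se", "p", "q", "tier", "family", "n_used"]
    ]


def write_results(results: pd.DataFrame, path) -> None:
    """Write an association results table as TSV."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
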