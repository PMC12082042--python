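"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, transitive closure, direct formulas) and shares no code with the
package's vectorized paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats

ISOTYPES = ("IgM", "IgD", "IgA1", "IgA2", "IgG1", "IgG2", "IgG3", "IgE")
SWITCHED = {"IgA1", "IgA2", "IgG1", "IgG2", "IgG3", "IgE"}


def _gene(call: str) -> str:
    return call.split(",")[0].split("*")[0].strip()


def brute_partition(rearrangements: pd.DataFrame, threshold: float) -> frozenset:
    """Clone partition by transitive closure over the all-pairs distance
    matrix, as a frozenset of frozensets of sequence_ids."""
    rows = rearrangements.to_dict("records")
    n = len(rows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        a, b = rows[i], rows[j]
        if _gene(a["v_call"]) != _gene(b["v_call"]):
            continue
        if _gene(a["j_call"]) != _gene(b["j_call"]):
            continue
        if len(a["junction"]) != len(b["junction"]):
            continue
        mismatches = sum(x != y for x, y in zip(a["junction"], b["junction"]))
        if mismatches / len(a["junction"]) <= threshold:
            parent[find(i)] = find(j)

    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(rows[i]["sequence_id"])
    return frozenset(frozenset(g) for g in groups.values())


def tally_isotype(clones: pd.DataFrame):
    """(counts, usage, expression) by explicit loop."""
    records = clones.to_dict("records")
    n_total = len(records)
    counts = {iso: 0 for iso in ISOTYPES}
    for r in records:
        counts[r["isotype"]] += 1
    usage = {iso: counts[iso] / n_total for iso in ISOTYPES}
    expression = {iso: np.log2(counts[iso] + 1) for iso in ISOTYPES}
    return counts, usage, expression


def tally_switching(clones: pd.DataFrame) -> float:
    records = clones.to_dict("records")
    hits = sum(1 for r in records if r["isotype"] in SWITCHED and r["mutated"])
    return hits / len(records)


def tally_v_allele(clones: pd.DataFrame):
    records = clones.to_dict("records")
    n_total = len(records)
    usage: dict[str, float] = {}
    switching: dict[str, float] = {}
    for r in records:
        if not r["mutated"]:
            continue
        usage[r["v_allele"]] = usage.get(r["v_allele"], 0) + 1
        if r["isotype"] in SWITCHED:
            switching[r["v_allele"]] = switching.get(r["v_allele"], 0) + 1
    usage = {a: c / n_total for a, c in usage.items()}
    switching = {a: switching.get(a, 0) / n_total for a in usage}
    return usage, switching


def tally_cdr3(clones: pd.DataFrame):
    records = clones.to_dict("records")
    lengths: dict[str, list] = {iso: [] for iso in ISOTYPES}
    for r in records:
        lengths[r["isotype"]].append(r["junction_length"])
    return {
        iso: (sum(v) / len(v) if v else None) for iso, v in lengths.items()
    }


def hill_direct(abundances, q: float) -> float:
    """Hill number at one order, in extended precision."""
    a = np.asarray(abundances, dtype=np.longdouble)
    p = a / a.sum()
    if q == 1.0:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float(((p ** np.longdouble(q)).sum()) ** (1.0 / (1.0 - q)))


def bh_direct(pvalues, m: int | None = None) -> list[float]:
    """Step-up BH by the textbook formula q_(i) = min_{j>=i} m p_(j)/j."""
    p = [float(x) for x in pvalues]
    n = len(p)
    m = n if m is None else m
    order = sorted(range(n), key=lambda i: (p[i], i))
    scaled = [m * p[i] / (rank + 1) for rank, i in enumerate(order)]
    # running minimum over the tail implements min_{j >= i}
    tail_min = [0.0] * n
    running = float("inf")
    for pos in range(n - 1, -1, -1):
        running = min(running, scaled[pos])
        tail_min[pos] = min(1.0, running)
    q = [0.0] * n
    for pos, i in enumerate(order):
        q[i] = tail_min[pos]
    return q


def ols_direct(X, y):
    """Normal-equations OLS with t-distribution p-values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - k)
    se = np.sqrt(np.diag(s2 * xtx_inv))
    t = beta / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), n - k)
    return beta, se, p


# --- random instance generators -----------------------------------------


def random_clustering_instance(rng, n_max: int = 30) -> pd.DataFrame:
    """Small rearrangement set with borderline junction distances."""
    n = int(rng.integers(2, n_max + 1))
    rows = []
    for i in range(n):
        length = int(rng.choice([9, 12]))
        rows.append(
            dict(
                sequence_id=f"S{i:03d}",
                participant_id="P1",
                v_call=str(rng.choice(["IGHV1-1*01", "IGHV1-1*02", "IGHV2-2*01"])),
                j_call=str(rng.choice(["IGHJ4", "IGHJ6"])),
                c_call="IGHM",
                junction="".join(rng.choice(list("AC"), size=length)),
                junction_length=length,
                mutation_count=int(rng.integers(0, 4)),
                duplicate_count=int(rng.integers(1, 4)),
            )
        )
    return pd.DataFrame(rows)


def random_clone_records(rng, n: int, participant: str = "P1") -> pd.DataFrame:
    """Random collapsed clone table for tally-oracle comparisons."""
    alleles = [f"IGHV{k}-1*01" for k in range(1, 7)]
    iso = rng.choice(ISOTYPES, size=n)
    return pd.DataFrame(
        {
            "participant_id": participant,
            "clone_id": [f"C{i:05d}" for i in range(n)],
            "isotype": iso,
            "v_allele": rng.choice(alleles, size=n),
            "j_gene": rng.choice(["IGHJ4", "IGHJ6"], size=n),
            "junction_length": rng.choice([45, 48, 51, 54], size=n).astype(int),
            "representative_junction": "ACG",
            "mutated": rng.random(n) < 0.6,
            "abundance": 1 + rng.poisson(2.0, size=n).astype(int),
            "n_members": 1,
            "max_mutation_count": 0,
        }
    )
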