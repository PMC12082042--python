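"""Clonal grouping and clone collapsing.

Sequences descending from one ancestral B-cell rearrangement share a V
gene, a J gene, a junction length, and a highly similar junction sequence.
Clones are inferred per participant by partitioning on (V gene, J gene,
junction length) and single-linkage clustering within each partition under
normalized Hamming distance on the junction: two sequences are linked iff
their distance is at most ``distance_threshold`` (default 0.15), and
connected components become clones.

Clones are then collapsed into clone–isotype units: one record per
(participant, clone, isotype subclass). These "unique BCR sequences" are
the counting units for every downstream repertoire measure; a clone
lineage that has switched class is countable once in each class it
appears in.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ContractError
from .io import REARRANGEMENT_FIELDS, first_call, map_isotype

log = logging.getLogger("ighrep")

DEFAULT_DISTANCE_THRESHOLD = 0.15

CLONE_TABLE_FIELDS = (
    "participant_id",
    "clone_id",
    "isotype",
    "v_allele",
    "j_gene",
    "junction_length",
    "representative_junction",
    "mutated",
    "abundance",
    "n_members",
    "max_mutation_count",
)


def gene_of(call: str) -> str:
    """Gene part of an IMGT-style call: first listed call, allele stripped."""
    return first_call(call).split("*")[0]


def _cluster_block(junctions: np.ndarray, threshold: float) -> np.ndarray:
    """Component labels for equal-length junctions under single linkage."""
    g = len(junctions)
    mat = np.frombuffer("".join(junctions).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(g, -1)
    dist = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    adj = csr_matrix(dist <= threshold)
    _, labels = connected_components(adj, directed=False)
    return labels


def assign_clones(
    rearrangements: pd.DataFrame,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> pd.DataFrame:
    """Assign a clone_id to every rearrangement row, cohort-wide.

    Partitions never cross participants, so the whole cohort can be
    processed in one call. The clone_id is the lexicographically smallest
    member sequence_id, which makes labels deterministic and invariant to
    input row order. Returns columns (sequence_id, participant_id, clone_id).
    """
    if not 0.0 <= distance_threshold <= 1.0:
        raise ContractError(f"distance_threshold {distance_threshold} not in [0, 1]")
    if rearrangements.empty:
        return pd.DataFrame(columns=["sequence_id", "participant_id", "clone_id"])
    if (rearrangements["junction"].str.len() == 0).any():
        raise ContractError("empty junction in input")

    df = rearrangements[["sequence_id", "participant_id", "v_call", "j_call",
                         "junction", "junction_length"]].reset_index(drop=True)
    df["v_gene"] = df["v_call"].map(gene_of)
    df["j_gene"] = df["j_call"].map(gene_of)
    key_cols = ["participant_id", "v_gene", "j_gene", "junction_length"]
    part_codes, _ = pd.factorize(pd.MultiIndex.from_frame(df[key_cols]))
    df["_part"] = part_codes

    clone_id = np.empty(len(df), dtype=object)
    sizes = df.groupby("_part")["_part"].transform("size").to_numpy()
    single = sizes == 1
    clone_id[single] = df["sequence_id"].to_numpy()[single]

    multi = df.loc[~single]
    for _, block in multi.groupby("_part", sort=False):
        labels = _cluster_block(block["junction"].to_numpy(), distance_threshold)
        seq = block["sequence_id"].to_numpy()
        # deterministic label: smallest member sequence_id per component
        for comp in np.unique(labels):
            members = labels == comp
            clone_id[block.index[members]] = seq[members].min()

    out = df[["sequence_id", "participant_id"]].copy()
    out["clone_id"] = clone_id
    if log.isEnabledFor(logging.INFO):
        log.info(
            "assigned %d sequences to %d clones across %d participants",
            len(out), out.groupby("participant_id")["clone_id"].nunique().sum(),
            out["participant_id"].nunique(),
        )
    return out


def group_clones(
    rearrangements: pd.DataFrame,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> pd.DataFrame:
    """Clone assignments for a single participant's rearrangements.

    Raises :class:`~ighrep.errors.ContractError` if rows span more than one
    participant; use :func:`assign_clones` for whole cohorts.
    """
    if rearrangements.empty:
        return pd.DataFrame(columns=["sequence_id", "participant_id", "clone_id"])
    participants = rearrangements["participant_id"].unique()
    if len(participants) > 1:
        raise ContractError(
            f"group_clones expects one participant, got {sorted(participants)}"
        )
    return assign_clones(rearrangements, distance_threshold)


def collapse_clones(
    rearrangements: pd.DataFrame,
    assignments: pd.DataFrame,
    mutation_gate: int = 1,
) -> pd.DataFrame:
    """Collapse rearrangements into clone–isotype units.

    One output record per (participant, clone, isotype subclass), with:

    * ``mutated`` — True iff any member sequence has
      ``mutation_count >= mutation_gate`` (gate default 1: one or more
      bases differing from the IMGT germline);
    * ``abundance`` — summed ``duplicate_count`` over member sequences;
    * ``v_allele`` — majority V allele among members, ties broken
      lexicographically;
    * ``representative_junction`` — junction of the highest-abundance
      member, ties broken lexicographically.
    """
    if mutation_gate < 1:
        raise ContractError(f"mutation_gate must be >= 1, got {mutation_gate}")
    cols = [c for c in REARRANGEMENT_FIELDS if c in rearrangements.columns]
    seq_in = set(rearrangements["sequence_id"])
    seq_asn = set(assignments["sequence_id"])
    if seq_asn - seq_in:
        missing = sorted(seq_asn - seq_in)[:5]
        raise ContractError(f"assignments reference unknown sequence_id(s): {missing}")
    if seq_in - seq_asn:
        missing = sorted(seq_in - seq_asn)[:5]
        raise ContractError(f"assignments do not cover sequence_id(s): {missing}")
    if rearrangements.empty:
        return pd.DataFrame(columns=CLONE_TABLE_FIELDS)

    df = rearrangements[cols].merge(
        assignments[["sequence_id", "clone_id"]], on="sequence_id", validate="1:1"
    )
    c_map = {c: map_isotype(c) for c in df["c_call"].unique()}
    df["isotype"] = df["c_call"].map(c_map)
    v_map = {v: first_call(v) for v in df["v_call"].unique()}
    df["v_allele"] = df["v_call"].map(v_map)
    j_map = {j: gene_of(j) for j in df["j_call"].unique()}
    df["j_gene"] = df["j_call"].map(j_map)
    df["_mut"] = df["mutation_count"] >= mutation_gate

    unit = ["participant_id", "clone_id", "isotype"]
    agg = df.groupby(unit, sort=True).agg(
        j_gene=("j_gene", "first"),
        mutated=("_mut", "any"),
        abundance=("duplicate_count", "sum"),
        n_members=("sequence_id", "size"),
        max_mutation_count=("mutation_count", "max"),
    )

    # majority V allele by member count, ties -> lexicographically smallest
    vc = df.groupby(unit + ["v_allele"], sort=True).size().reset_index(name="n")
    vc = vc.sort_values(unit + ["n", "v_allele"], ascending=[True] * 3 + [False, True])
    majority = vc.drop_duplicates(unit).set_index(unit)["v_allele"]
    agg["v_allele"] = majority

    # representative junction: highest duplicate_count, ties -> smallest string
    rep = df.sort_values(unit + ["duplicate_count", "junction"],
                         ascending=[True] * 3 + [False, True])
    rep = rep.drop_duplicates(unit).set_index(unit)
    agg["representative_junction"] = rep["junction"]
    agg["junction_length"] = rep["junction"].str.len().astype(np.int64)

    out = agg.reset_index()[list(CLONE_TABLE_FIELDS)]
    log.info(
        "collapsed %d sequences into %d clone-isotype units", len(df), len(out)
    )
    return out


def write_clone_table(df: pd.DataFrame, path) -> None:
    """Write the collapsed clone table as TSV."""
    df.to_csv(path, sep="\t", index=False)
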