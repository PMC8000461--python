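"""Incremental LIN assignment: the heart of the pipeline.

Adding a genome runs a two-step nearest-genome search followed by exactly one
precise ANI computation:

1. The query's k=21 signature is compared against the representative of every
   existing 95%-level LINgroup. The best Jaccard similarity J is bracketed:
   J > 0.2475 places the query inside that representative's group
   (~ANI >= 95%); 0.0025 < J <= 0.2475 means some stored genome shares at
   least 70% ANI; J <= 0.0025 means nothing in the store is related at the
   70% level and the query founds a new top-level branch with no ANI
   computation at all.
2. Within the chosen group, the most similar member is found by Jaccard at
   k=51 (same group — high resolution) or k=21 (shared top level only), and
   reciprocal fragment-based ANI is computed against that single subject.

The new LIN copies the subject's LIN through every position whose ANI
threshold the measured ANI reaches, takes a fresh number (smallest unused
under that prefix) at the first position it fails, and zero-fills the rest.
Both Jaccard cutoffs are empirical calibrations at k=21, n=2000 — they are
configuration, not derived quantities.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

from . import ani as ani_mod
from .io import read_fasta
from .scheme import LINScheme
from .sketch import Signature, compute_signature, jaccard
from .store import Store

logger = logging.getLogger(__name__)

#: Jaccard (k=21, n=2000) above which the query joins an existing
#: grouping-level (95% ANI) LINgroup
JACCARD_SAME_GROUP = 0.2475
#: Jaccard (k=21, n=2000) at or below which no stored genome reaches 70% ANI
JACCARD_NOVEL = 0.0025


class Bracket(enum.Enum):
    SAME_F_GROUP = "same_f_group"
    SHARED_A = "shared_a"
    NOVEL = "novel"


@dataclass(frozen=True)
class SearchOutcome:
    bracket: Bracket
    best_subject: str | None
    jaccard: float


@dataclass
class AddReport:
    """Audit record of one add-genome event."""

    genome_id: str
    bracket: Bracket
    jaccard: float | None
    subject_id: str | None
    ani: float | None
    lins: dict[str, list[int]] = field(default_factory=dict)


def classify_query(
    query_sig: Signature,
    representatives: dict[str, Signature],
    insertion_order: dict[str, int] | None = None,
    upper: float = JACCARD_SAME_GROUP,
    lower: float = JACCARD_NOVEL,
) -> SearchOutcome:
    """Bracket the query by its best Jaccard against group representatives.

    ``representatives`` maps genome_id to that representative's k=21
    signature. Ties on J are broken by lowest insertion order (dict order
    when no order mapping is given). An empty store is NOVEL by definition.
    """
    if not representatives:
        return SearchOutcome(Bracket.NOVEL, None, 0.0)
    order = insertion_order or {gid: i for i, gid in enumerate(representatives)}
    best_id, best_j = None, -1.0
    for gid, sig in representatives.items():
        j = jaccard(query_sig, sig)
        if j > best_j or (j == best_j and order[gid] < order[best_id]):
            best_id, best_j = gid, j
    if best_j > upper:
        return SearchOutcome(Bracket.SAME_F_GROUP, best_id, best_j)
    if best_j > lower:
        return SearchOutcome(Bracket.SHARED_A, best_id, best_j)
    return SearchOutcome(Bracket.NOVEL, None, best_j)


def most_similar_in_group(
    query_sigs: dict[int, Signature],
    members: dict[str, dict[int, Signature]],
    bracket: Bracket,
    insertion_order: dict[str, int] | None = None,
    k_pair: tuple[int, int] = (21, 51),
) -> tuple[str, float]:
    """Best member of the candidate group by Jaccard.

    Resolution follows the bracket: within the same grouping-level LINgroup
    the long k-mer (k=51) discriminates highly similar genomes; across groups
    that merely share the top level, the short k-mer (k=21) retains signal.
    """
    if not members:
        raise ValueError("empty member list")
    if bracket is Bracket.NOVEL:
        raise ValueError("no group search for a NOVEL query")
    k = k_pair[1] if bracket is Bracket.SAME_F_GROUP else k_pair[0]
    order = insertion_order or {gid: i for i, gid in enumerate(members)}
    best_id, best_j = None, -1.0
    for gid, sigs in members.items():
        j = jaccard(query_sigs[k], sigs[k])
        if j > best_j or (j == best_j and order[gid] < order[best_id]):
            best_id, best_j = gid, j
    return best_id, best_j


def assign_lin(
    subject_lin: list[int] | None,
    ani: float | None,
    scheme: LINScheme,
    store: Store,
) -> list[int]:
    """Derive the query's LIN from its subject's LIN and the measured ANI.

    Copies the subject prefix through the last position whose threshold the
    ANI reaches, allocates the smallest unused number at the next position,
    and zero-fills the remainder. With no subject (first genome or NOVEL
    bracket) the "prefix" is empty: the first genome gets all zeros and later
    novel genomes a fresh top-position number. An ANI at or above the final
    threshold copies the subject LIN entirely (deliberately duplicate LINs;
    identity lives in the genome id).
    """
    if subject_lin is None:
        if store.genome_count() <= 1:
            return scheme.zeros()
        number = store.allocate_number(scheme, [], 0)
        return [number] + [0] * (len(scheme) - 1)
    if len(subject_lin) != len(scheme):
        raise ValueError("subject LIN length does not match scheme")
    depth = scheme.shared_depth(ani)
    if depth == len(scheme):
        return list(subject_lin)
    prefix = list(subject_lin[:depth])
    number = store.allocate_number(scheme, prefix, depth)
    return prefix + [number] + [0] * (len(scheme) - depth - 1)


def add_genome(
    fasta_path,
    store: Store,
    taxonomy: dict | None = None,
    genome_id: str | None = None,
    k_pair: tuple[int, int] = (21, 51),
    sketch_size: int = 2000,
    upper: float = JACCARD_SAME_GROUP,
    lower: float = JACCARD_NOVEL,
    ani_params: dict | None = None,
) -> AddReport:
    """Run the full add-genome flow and persist every artifact.

    Register -> sketch at both k values -> bracket against representatives ->
    (unless NOVEL) find the most similar group member and compute one
    reciprocal ANI -> assign a LIN under every active scheme -> save LINs,
    the ANI record and the signature files (with representative promotion
    when a new group is founded).
    """
    ani_params = ani_params or {}
    record = store.register_genome(fasta_path, taxonomy=taxonomy, genome_id=genome_id)
    gid = record.genome_id
    try:
        store.get_lin(gid, store.grouping_scheme.name)
    except KeyError:
        pass
    else:  # idempotent re-add of an already assigned genome
        return AddReport(
            genome_id=gid, bracket=Bracket.NOVEL, jaccard=None, subject_id=None, ani=None,
            lins={name: store.get_lin(gid, name) for name in store.active_schemes},
        )

    seqs = read_fasta(record.fasta_path)
    sigs = {k: compute_signature(seqs, k=k, n=sketch_size, genome_id=gid) for k in k_pair}
    orders = {g.genome_id: g.insertion_order for g in store.genomes()}

    reps = {g: s[k_pair[0]] for g, s in store.representative_signatures().items()}
    outcome = classify_query(sigs[k_pair[0]], reps, orders, upper=upper, lower=lower)

    subject_id: str | None = None
    ani_value: float | None = None
    if outcome.bracket is not Bracket.NOVEL:
        group_prefix = store.group_prefix_of(outcome.best_subject)
        member_ids = store.members_of(group_prefix)
        members = {m: store.load_member_signatures(m) for m in member_ids}
        subject_id, best_j = most_similar_in_group(
            sigs, members, outcome.bracket, orders, k_pair=k_pair
        )
        subject_seqs = read_fasta(store.genome(subject_id).fasta_path)
        try:
            ani_value = ani_mod.reciprocal_ani(seqs, subject_seqs, gid, subject_id, **ani_params)
        except ani_mod.NoSignificantSimilarity:
            warnings.warn(
                f"{gid}: Jaccard bracket {outcome.bracket.value} but precise ANI found "
                "no significant similarity; treating as novel (sketch calibration disagreement)",
            )
            outcome = SearchOutcome(Bracket.NOVEL, None, outcome.jaccard)
            subject_id = None

    report = AddReport(
        genome_id=gid,
        bracket=outcome.bracket,
        jaccard=outcome.jaccard,
        subject_id=subject_id,
        ani=ani_value,
    )
    for name in store.active_schemes:
        scheme = store.get_scheme(name)
        subject_lin = store.get_lin(subject_id, name) if subject_id else None
        lin = assign_lin(subject_lin, ani_value, scheme, store)
        store.save_lin(gid, name, lin)
        report.lins[name] = lin
    if subject_id is not None:
        store.record_ani(gid, subject_id, ani_value)
    store.save_member_signature(gid, sigs)
    logger.info(
        "added %s: bracket=%s J=%.4f subject=%s ANI=%s",
        gid, outcome.bracket.value, outcome.jaccard, subject_id,
        f"{ani_value:.4f}" if ani_value is not None else "-",
    )
    return report
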