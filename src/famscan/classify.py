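"""Genome scanning, best-E-value classification, ortholog calls, presence/absence.

The pipeline stage this module implements: translated peptide segments
from draft-genome contigs are scored against every calibrated profile in
a subfamily library; significant hits populate a classification matrix
(profiles x targets); each target is assigned to the subfamily whose
profile achieves the best (smallest) E-value; assignments are reciprocally
validated against the full library including decoy profiles; hits are
aggregated into per-(species, subfamily) ortholog calls requiring
multi-region (exon-level) evidence; and accepted calls are reduced to a
species x subfamily presence/absence matrix with gain/loss events placed
on a species tree by parsimony.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import dendropy
import numpy as np

from .profilehmm import LN2, ProfileHMM, evalue, forward_batch_raw, viterbi
from .seqkit import NucContig, PeptideSegment, six_frame_segments
from .subfamlib import HmmLibrary
from .substitution import encode_protein

DEFAULT_E_MAX = 1e-5
DEFAULT_EXON_EVIDENCE_MIN = 2


@dataclass
class Hit:
    """One accepted profile-vs-segment match mapped to contig coordinates."""

    target_id: str
    contig_id: str
    species: str
    region: str
    subfamily: str
    bit_score: float
    evalue: float
    nuc_start: int
    nuc_end: int
    strand: str
    frame: int
    aa_start: int
    aa_end: int
    reciprocal_ok: bool | None = None
    reciprocal_best: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.nuc_start, self.nuc_end)


class ColumnCall(NamedTuple):
    subfamily: str
    evalue: float
    ambiguous: bool


@dataclass
class ClassificationMatrix:
    """E-values/bit scores of every profile row against every target column.

    Rows are subfamily identities; columns are (target id, region) pairs so
    the same sequence scanned in two fragment regions occupies two columns.
    """

    rows: list[str] = field(default_factory=list)
    cols: list[tuple[str, str]] = field(default_factory=list)
    cells: dict[tuple[str, tuple[str, str]], tuple[float, float]] = field(
        default_factory=dict)

    def set_cell(self, row: str, col: tuple[str, str],
                 evalue_: float, bit_score: float) -> None:
        if not (math.isfinite(evalue_) and evalue_ >= 0):
            raise ValueError(f"invalid e-value {evalue_!r}")
        if row not in self.rows:
            self.rows.append(row)
        if col not in self.cols:
            self.cols.append(col)
        self.cells[(row, col)] = (evalue_, bit_score)

    def column_cells(self, col: tuple[str, str]) -> dict[str, tuple[float, float]]:
        return {r: self.cells[(r, col)] for r in self.rows if (r, col) in self.cells}


def classify_column(matrix: ClassificationMatrix, col: tuple[str, str]) -> ColumnCall:
    """Assign the column's target to the row (subfamily) with minimum E-value.

    Ties on E-value are broken by higher bit score, then lexicographically
    smaller subfamily name, and the call is flagged ambiguous.
    """
    cells = matrix.column_cells(col)
    if not cells:
        raise ValueError(f"column {col!r} is empty")
    ranked = sorted(cells.items(), key=lambda kv: (kv[1][0], -kv[1][1], kv[0]))
    best_row, (best_e, _) = ranked[0]
    ambiguous = len(ranked) > 1 and ranked[1][1][0] == best_e
    return ColumnCall(subfamily=best_row, evalue=best_e, ambiguous=ambiguous)


def matrix_from_hits(hits: list[Hit]) -> ClassificationMatrix:
    """Best hit per (subfamily, (target, region)) cell."""
    m = ClassificationMatrix()
    for h in sorted(hits, key=lambda h: h.evalue, reverse=True):
        m.set_cell(h.subfamily, (h.target_id, h.region), h.evalue, h.bit_score)
    return m


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_genome(contigs: list[NucContig], library: HmmLibrary,
                e_max: float = DEFAULT_E_MAX, min_len: int = 20,
                merge_overlaps: bool = True) -> list[Hit]:
    """Score all six-frame peptide segments against every library profile.

    E-values use the number of scanned segments as the target count.  Hits
    with E <= e_max are mapped back to forward-strand contig coordinates
    through the Viterbi alignment span.  Overlapping hits of the same
    subfamily on one segment keep only the best E-value.
    """
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    segments: list[PeptideSegment] = []
    for contig in contigs:
        segments.extend(six_frame_segments(contig, min_len=min_len))
    if not segments:
        return []
    n_targets = len(segments)
    encoded = [encode_protein(s.aa_seq) for s in segments]
    hits: list[Hit] = []
    for hmm in library.profiles.values():
        if hmm.calibration is None:
            raise ValueError(f"profile {hmm.name!r} is not calibrated")
        bits = forward_batch_raw(hmm, encoded) / LN2
        evals = np.array([evalue(hmm, float(b), n_targets) for b in bits])
        for i in np.nonzero(evals <= e_max)[0]:
            seg = segments[i]
            vr = viterbi(hmm, seg.aa_seq)
            if seg.strand == "+":
                nuc_start = seg.nuc_start + 3 * vr.target_start
                nuc_end = seg.nuc_start + 3 * vr.target_end
            else:
                nuc_start = seg.nuc_end - 3 * vr.target_end
                nuc_end = seg.nuc_end - 3 * vr.target_start
            hits.append(Hit(
                target_id=seg.id, contig_id=seg.contig_id, species=seg.species,
                region=hmm.region, subfamily=hmm.subfamily,
                bit_score=float(bits[i]), evalue=float(evals[i]),
                nuc_start=nuc_start, nuc_end=nuc_end, strand=seg.strand,
                frame=seg.frame, aa_start=vr.target_start, aa_end=vr.target_end))
    if merge_overlaps:
        hits = merge_overlapping_hits(hits)
    return sorted(hits, key=lambda h: (h.species, h.contig_id, h.nuc_start, h.evalue))


def merge_overlapping_hits(hits: list[Hit]) -> list[Hit]:
    """Within one segment and subfamily, keep the best E-value among overlaps."""
    kept: list[Hit] = []
    by_group: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        by_group.setdefault((h.target_id, h.subfamily), []).append(h)
    for group in by_group.values():
        group.sort(key=lambda h: h.evalue)
        chosen: list[Hit] = []
        for h in group:
            if any(h.nuc_start < c.nuc_end and c.nuc_start < h.nuc_end
                   for c in chosen):
                continue
            chosen.append(h)
        kept.extend(chosen)
    return kept


def reciprocal_validate(peptide: str, library: HmmLibrary,
                        assigned_subfamily: str) -> tuple[str, bool]:
    """Search a hit's peptide back against the whole library (with decoys).

    Returns the best-scoring profile's name and whether its subfamily
    agrees with the forward-search assignment.  With no decoys and a
    single-subfamily library the check is vacuous; callers should log it
    as untested.
    """
    profiles = library.all_profiles(include_decoys=True)
    if not profiles:
        raise ValueError("empty library")
    enc = [encode_protein(peptide)]
    best_name, best_sf, best_bits = "", "", -np.inf
    for hmm in profiles:
        b = float(forward_batch_raw(hmm, enc)[0]) / LN2
        if b > best_bits:
            best_name, best_sf, best_bits = hmm.name, hmm.subfamily, b
    return best_name, best_sf == assigned_subfamily


def validate_hits(hits: list[Hit], library: HmmLibrary,
                  peptides: dict[str, str]) -> list[Hit]:
    """Fill reciprocal_ok on each hit, scoring each unique segment once."""
    profiles = library.all_profiles(include_decoys=True)
    unique = sorted({h.target_id for h in hits})
    enc = [encode_protein(peptides[t]) for t in unique]
    if not unique:
        return hits
    scores = np.stack([forward_batch_raw(hmm, enc) for hmm in profiles])  # (P, T)
    best_idx = scores.argmax(axis=0)
    best_for = {t: profiles[best_idx[i]] for i, t in enumerate(unique)}
    for h in hits:
        best = best_for[h.target_id]
        h.reciprocal_best = best.name
        h.reciprocal_ok = best.subfamily == h.subfamily
    return hits


# ---------------------------------------------------------------------------
# ortholog calls
# ---------------------------------------------------------------------------

@dataclass
class OrthologyCall:
    gene_id: str
    species: str
    subfamily: str
    n_regions_hit: int
    reciprocal_ok: bool
    status: str  # accepted | ambiguous | rejected
    hits: list[Hit] = field(default_factory=list)


def winning_hits(hits: list[Hit]) -> list[Hit]:
    """Reduce hits to the best-E-value winner of each (target, region) column.

    Profiles from every subfamily legitimately match every family member;
    a target's subfamily assignment is the column winner, so downstream
    ortholog evidence counts winners only.  Ties are broken by higher bit
    score, then subfamily name.
    """
    by_col: dict[tuple[str, str], Hit] = {}
    for h in sorted(hits, key=lambda h: (h.evalue, -h.bit_score, h.subfamily)):
        by_col.setdefault((h.target_id, h.region), h)
    return list(by_col.values())


def call_orthologs(hits: list[Hit],
                   exon_evidence_min: int = DEFAULT_EXON_EVIDENCE_MIN,
                   winners_only: bool = True) -> list[OrthologyCall]:
    """Aggregate hits into per-(species, subfamily) ortholog calls.

    Hits are first reduced to per-(target, region) column winners (the
    best-E-value classification rule); distinct fragment regions are then
    counted across contigs — exons of one gene scattered over several
    small contigs still accumulate evidence.  A call is accepted when it
    has winning hits in at least exon_evidence_min regions and every such
    hit passed reciprocal validation; fewer regions give an ambiguous
    call, and any reciprocal failure rejects the call.
    """
    if winners_only:
        hits = winning_hits(hits)
    groups: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        groups.setdefault((h.species, h.subfamily), []).append(h)
    calls = []
    for (species, subfamily), group in sorted(groups.items()):
        regions = {h.region for h in group}
        recip = all(h.reciprocal_ok is not False for h in group)
        if not recip:
            status = "rejected"
        elif len(regions) >= exon_evidence_min:
            status = "accepted"
        else:
            status = "ambiguous"
        calls.append(OrthologyCall(
            gene_id=f"{species}|{subfamily}", species=species,
            subfamily=subfamily, n_regions_hit=len(regions),
            reciprocal_ok=recip, status=status, hits=sorted(
                group, key=lambda h: h.evalue)))
    return calls


# ---------------------------------------------------------------------------
# presence/absence with parsimony gain/loss events
# ---------------------------------------------------------------------------

@dataclass
class GeneEvent:
    subfamily: str
    node: str        # taxon label for leaves, clade leafset string otherwise
    kind: str        # gain | loss
    ambiguous: bool = False


@dataclass
class PresenceAbsenceMatrix:
    species: list[str]
    subfamilies: list[str]
    states: dict[tuple[str, str], str]  # present | absent | unknown
    events: list[GeneEvent] = field(default_factory=list)
    parsimony_score: dict[str, int] = field(default_factory=dict)

    def state(self, species: str, subfamily: str) -> str:
        return self.states[(species, subfamily)]

    def to_tsv(self, path: str) -> None:
        symbol = {"present": "1", "absent": "0", "unknown": "?"}
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.subfamilies) + "\n")
            for sp in self.species:
                cells = [symbol[self.states[(sp, sf)]] for sf in self.subfamilies]
                fh.write(sp + "\t" + "\t".join(cells) + "\n")


def annotated_newick(pam: "PresenceAbsenceMatrix",
                     species_tree: dendropy.Tree) -> str:
    """Newick string with gain/loss events as node annotations.

    Each node that hosts events gets a label like ``+S1|-S2`` (gain of S1,
    loss of S2); an ambiguous placement is suffixed with ``?``.
    """
    tree = species_tree.clone(depth=1)
    by_node: dict[str, list[str]] = {}
    for e in pam.events:
        tag = ("+" if e.kind == "gain" else "-") + e.subfamily
        if e.ambiguous:
            tag += "?"
        by_node.setdefault(e.node, []).append(tag)
    for node in tree.preorder_node_iter():
        label = _node_label(node)
        tags = by_node.get(label)
        if not tags:
            continue
        if node.is_leaf():
            node.taxon.label = f"{node.taxon.label}[{'|'.join(tags)}]"
        else:
            node.label = "|".join(tags)
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def _node_label(node: dendropy.Node) -> str:
    leaves = sorted(t.taxon.label for t in node.leaf_iter())
    return leaves[0] if len(leaves) == 1 else "{" + ",".join(leaves) + "}"


def _fitch_events(tree: dendropy.Tree, tip_states: dict[str, int | None],
                  subfamily: str) -> tuple[list[GeneEvent], int]:
    """Binary Fitch parsimony with an implicit absent state above the root.

    Tips with state None (unknown) carry the full state set.  Returns the
    gain/loss events (the origin of a family counts as a gain on the edge
    into the first present node) and the parsimony score (number of state
    changes within the tree, excluding the implicit root-edge gain).
    """
    sets: dict[dendropy.Node, frozenset[int]] = {}
    score = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states.get(node.taxon.label)
            sets[node] = frozenset({0, 1}) if s is None else frozenset({s})
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[node] = inter
            else:
                sets[node] = frozenset.union(*child_sets)
                score += 1
    events: list[GeneEvent] = []
    states: dict[dendropy.Node, int] = {}
    root = tree.seed_node
    root_set = sets[root]
    root_ambiguous = len(root_set) == 2
    # implicit ancestral state is absent; a present root is an initial gain
    states[root] = 0 if root_ambiguous else next(iter(root_set))
    if states[root] == 1:
        events.append(GeneEvent(subfamily, _node_label(root), "gain",
                                ambiguous=root_ambiguous))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[node.parent_node]
        s = sets[node]
        ambiguous = len(s) == 2
        state = parent_state if parent_state in s else next(iter(s))
        states[node] = state
        if state != parent_state:
            kind = "gain" if state == 1 else "loss"
            events.append(GeneEvent(subfamily, _node_label(node), kind,
                                    ambiguous=ambiguous))
    return events, score


def _dollo_events(tree: dendropy.Tree, tip_states: dict[str, int | None],
                  subfamily: str) -> tuple[list[GeneEvent], int]:
    """Single-gain (Dollo) reconstruction: one gain at the MRCA of present
    tips, losses on the maximal subtrees below it containing no present tip."""
    present = [l for l, s in tip_states.items() if s == 1]
    if not present:
        return [], 0
    taxa = [t for t in tree.taxon_namespace if t.label in set(present)]
    mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else \
        next(l for l in tree.leaf_node_iter() if l.taxon.label == present[0])
    events = [GeneEvent(subfamily, _node_label(mrca), "gain")]
    n_losses = 0

    def descend(node: dendropy.Node) -> None:
        nonlocal n_losses
        for child in node.child_nodes():
            tips = {t.taxon.label for t in child.leaf_iter()}
            if not any(tip_states.get(t) == 1 for t in tips):
                if any(tip_states.get(t) == 0 for t in tips):
                    events.append(GeneEvent(subfamily, _node_label(child), "loss"))
                    n_losses += 1
            else:
                descend(child)

    descend(mrca)
    return events, n_losses


def presence_absence(calls: list[OrthologyCall], species_tree: dendropy.Tree,
                     subfamilies: list[str] | None = None,
                     scanned_species: set[str] | None = None,
                     method: str = "fitch") -> PresenceAbsenceMatrix:
    """Reduce accepted calls to a species x subfamily matrix with events.

    A cell is present iff the species has at least one accepted call for
    the subfamily, absent if the species was scanned without one, and
    unknown if the species was never scanned (unknown cells enter the
    parsimony reconstruction as missing data).
    """
    species_tree = species_tree.clone(depth=1)
    species_tree.is_rooted = True  # reconstruction reads the tree as rooted
    tree_species = [leaf.taxon.label for leaf in species_tree.leaf_node_iter()]
    call_species = {c.species for c in calls}
    missing = call_species - set(tree_species)
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    if subfamilies is None:
        subfamilies = sorted({c.subfamily for c in calls})
    if scanned_species is None:
        scanned_species = set(tree_species)
    accepted = {(c.species, c.subfamily) for c in calls if c.status == "accepted"}
    states: dict[tuple[str, str], str] = {}
    events: list[GeneEvent] = []
    scores: dict[str, int] = {}
    for sf in subfamilies:
        tip_states: dict[str, int | None] = {}
        for sp in tree_species:
            if sp not in scanned_species:
                states[(sp, sf)] = "unknown"
                tip_states[sp] = None
            elif (sp, sf) in accepted:
                states[(sp, sf)] = "present"
                tip_states[sp] = 1
            else:
                states[(sp, sf)] = "absent"
                tip_states[sp] = 0
        if method == "fitch":
            ev, score = _fitch_events(species_tree, tip_states, sf)
        elif method == "dollo":
            ev, score = _dollo_events(species_tree, tip_states, sf)
        else:
            raise ValueError("method must be 'fitch' or 'dollo'")
        events.extend(ev)
        scores[sf] = score
    return PresenceAbsenceMatrix(species=tree_species, subfamilies=list(subfamilies),
                                 states=states, events=events,
                                 parsimony_score=scores)


# ---------------------------------------------------------------------------
# worked-example matrix shipped as package data
# ---------------------------------------------------------------------------

def load_worked_example() -> dict[str, ClassificationMatrix]:
    """Load the packaged worked-example classification matrices.

    The table transcribes published subfamily-profile search scores for
    little-skate and sea-lamprey genome sequences (five subfamily profile
    rows per column; columns are sequence/contig identifiers paired with
    the fragment region scanned).  Values are transcribed verbatim from
    the printed source, including two suspected typographical oddities in
    the skate block, which are preserved rather than corrected.
    """
    matrices: dict[str, ClassificationMatrix] = {}
    path = resources.files("famscan.data") / "worked_example_scores.tsv"
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            genome = row["genome"]
            m = matrices.setdefault(genome, ClassificationMatrix())
            bits = float(row["bit_score"].replace(",", "."))
            m.set_cell(row["subfamily"], (row["target"], row["region"]),
                       float(row["evalue"]), bits)
    return matrices


def load_worked_example_best() -> dict[str, dict[tuple[str, str], tuple[str, float]]]:
    """Expected best (subfamily, e-value) per column, from the printed boldface."""
    best: dict[str, dict[tuple[str, str], tuple[str, float]]] = {}
    path = resources.files("famscan.data") / "worked_example_scores.tsv"
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if row["best"] == "1":
                best.setdefault(row["genome"], {})[(row["target"], row["region"])] = (
                    row["subfamily"], float(row["evalue"]))
    return best


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

HIT_TSV_COLUMNS = ("contig", "start", "end", "strand", "frame", "region",
                   "subfamily", "bits", "evalue", "reciprocal_ok", "species",
                   "target", "aa_start", "aa_end")


def write_hits_tsv(path: str, hits: list[Hit]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HIT_TSV_COLUMNS)
        for h in hits:
            recip = "" if h.reciprocal_ok is None else int(h.reciprocal_ok)
            w.writerow([h.contig_id, h.nuc_start, h.nuc_end, h.strand, h.frame,
                        h.region, h.subfamily, f"{h.bit_score:.4f}",
                        f"{h.evalue:.6e}", recip, h.species, h.target_id,
                        h.aa_start, h.aa_end])


def read_hits_tsv(path: str) -> list[Hit]:
    hits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            recip = row["reciprocal_ok"]
            hits.append(Hit(
                target_id=row["target"], contig_id=row["contig"],
                species=row["species"], region=row["region"],
                subfamily=row["subfamily"], bit_score=float(row["bits"]),
                evalue=float(row["evalue"]), nuc_start=int(row["start"]),
                nuc_end=int(row["end"]), strand=row["strand"],
                frame=int(row["frame"]), aa_start=int(row["aa_start"]),
                aa_end=int(row["aa_end"]),
                reciprocal_ok=None if recip == "" else bool(int(recip))))
    return hits


def write_matrix_tsv(path: str, matrix: ClassificationMatrix) -> None:
    with open(path, "w") as fh:
        headers = [f"{t}|{r}" for t, r in matrix.cols]
        fh.write("profile\t" + "\t".join(headers) + "\n")
        for row in matrix.rows:
            cells = []
            for col in matrix.cols:
                cell = matrix.cells.get((row, col))
                cells.append("" if cell is None else f"{cell[0]:.2e} ({cell[1]:.1f})")
            fh.write(row + "\t" + "\t".join(cells) + "\n")


def write_calls_tsv(path: str, calls: list[OrthologyCall]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies\tsubfamily\tn_regions_hit\treciprocal_ok\tstatus\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.species}\t{c.subfamily}\t{c.n_regions_hit}\t"
                     f"{int(c.reciprocal_ok)}\t{c.status}\n")
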