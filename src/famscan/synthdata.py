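"""Synthetic gene families, draft genomes, and truth tables.

The generator emulates the data regime the pipeline is built for: a
K-subfamily GPCR-like protein family that diverged from a single ancestor,
each subfamily carrying its own set of slowly-evolving diagnostic motif
columns; one subfamily lacking the C-terminal cytoplasmic tail; gene
copies duplicated and lost along a species tree by Poisson processes; and
tip genes reverse-translated, split into exons, and scattered across
small background contigs on random strands — the fragmented
draft-assembly condition that motivates fragment-region profile searches.

Every output is a pure function of (config, seed).  The truth table
(planted exon coordinates, subfamily labels, loss events) is the scoring
surface for end-to-end recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .phylo import SubstModel, discrete_gamma_rates, transition_matrix
from .seqkit import MsAlignment, NucContig, reverse_complement, translate
from .subfamlib import FragmentRegion
from .substitution import AMINO_ACIDS, N_AA, JTT_FREQS

#: 12-tip species tree spanning shallow and deep divergences (root-to-tip
#: depth ~0.4 expected substitutions per site), shipped as the default
#: study condition.
DEFAULT_SPECIES_TREE = (
    "((((sp01:0.08,sp02:0.08):0.07,(sp03:0.10,sp04:0.05):0.05):0.10,"
    "((sp05:0.12,sp06:0.12):0.08,sp07:0.20):0.05):0.15,"
    "(((sp08:0.10,sp09:0.10):0.10,sp10:0.20):0.10,"
    "(sp11:0.15,sp12:0.15):0.15):0.10);"
)

# codons per amino acid under the standard code, for uniform reverse translation
_CODONS_BY_AA: dict[str, list[str]] = {}
from .seqkit import CODON_TO_AA  # noqa: E402

for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


@dataclass
class SimConfig:
    """Study conditions for the synthetic family and genomes."""

    species_tree_newick: str = DEFAULT_SPECIES_TREE
    n_subfamilies: int = 5
    root_length: int = 350
    b_sub: float = 0.7            # branch from family root to each subfamily ancestor
    alpha: float = 1.0            # gamma shape of among-site rate variation
    n_categories: int = 4
    n_motif_cols: int = 15        # diagnostic columns per subfamily
    motif_rate: float = 0.05      # rate multiplier on a subfamily's own motifs
    tail_subfamily: str = "S1"    # subfamily lacking the C-terminal tail
    tail_len: int = 50
    lambda_dup: float = 0.05      # duplications per unit branch length
    lambda_loss: float = 0.30     # losses per unit branch length
    exons_per_gene: int = 3
    min_exon_aa: int = 25
    intron_len_range: tuple[int, int] = (60, 200)
    flank_len_range: tuple[int, int] = (100, 400)
    fragmentation_rate: float = 0.5  # P(gene's exons land on separate contigs)
    n_decoy_contigs: int = 3
    decoy_contig_len: int = 900

    def __post_init__(self) -> None:
        if self.n_subfamilies < 2:
            raise ValueError("need K >= 2 subfamilies")
        for rate in (self.lambda_dup, self.lambda_loss, self.motif_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.n_motif_cols * self.n_subfamilies > self.root_length - self.tail_len:
            raise ValueError("motif columns do not fit in the untailed region")
        if self.exons_per_gene * self.min_exon_aa > self.root_length - self.tail_len:
            raise ValueError("exons do not fit the protein length")

    @property
    def subfamily_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_subfamilies)]

    def species_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.species_tree_newick, schema="newick",
                                 preserve_underscores=True)


@dataclass
class SimProtein:
    id: str
    species: str
    subfamily: str
    seq: str


@dataclass
class SimEvent:
    subfamily: str
    branch: str   # label of the clade below the branch the event occurred on
    kind: str     # duplication | loss
    copy_id: str


@dataclass
class FamilySimulation:
    config: SimConfig
    seed: int
    proteins: list[SimProtein]
    events: list[SimEvent]
    motif_columns: dict[str, np.ndarray]
    site_rates: np.ndarray
    gene_trees: dict[str, str]

    def presence(self) -> dict[tuple[str, str], bool]:
        tree = self.config.species_tree()
        species = [l.taxon.label for l in tree.leaf_node_iter()]
        out = {(sp, sf): False for sp in species
               for sf in self.config.subfamily_names}
        for p in self.proteins:
            out[(p.species, p.subfamily)] = True
        return out

    def alignment(self) -> MsAlignment:
        """Tip proteins as an alignment (no indels are simulated, so
        sequences align column-for-column; tail-less rows are gap-padded)."""
        full = self.config.root_length
        rows = []
        labels = {}
        for p in self.proteins:
            rows.append((p.id, p.seq + "-" * (full - len(p.seq))))
            labels[p.id] = p.subfamily
        return MsAlignment(rows, labels)


def default_regions(config: SimConfig) -> list[FragmentRegion]:
    """Four fragment regions mirroring transmembrane-domain landmarks.

    Intervals are fractions of the protein body and deliberately exclude
    the C-terminal tail so tail-less subfamilies train on equal footing.
    """
    body = config.root_length - config.tail_len
    f = lambda x: int(round(x * body))
    return [
        FragmentRegion("TM1-4", f(0.03), f(0.43)),
        FragmentRegion("TM4-5", f(0.43), f(0.70)),
        FragmentRegion("TM6", f(0.72), f(0.85)),
        FragmentRegion("TM6-7", f(0.85), f(1.0)),
    ]


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _evolve(seq_codes: np.ndarray, branch_len: float, site_rates: np.ndarray,
            model: SubstModel, rng: np.random.Generator) -> np.ndarray:
    """Evolve integer-encoded residues along one branch, per-site rates given."""
    if branch_len <= 0:
        return seq_codes.copy()
    child = seq_codes.copy()
    for rate in np.unique(site_rates):
        idx = np.nonzero(site_rates == rate)[0]
        if rate == 0.0:
            continue
        p = transition_matrix(model, branch_len, float(rate))
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(idx))
        child[idx] = np.array([np.searchsorted(cum[seq_codes[i]], uu)
                               for i, uu in zip(idx, u)])
        np.clip(child, 0, N_AA - 1, out=child)
    return child


def simulate_family(config: SimConfig, seed: int) -> FamilySimulation:
    """Simulate the family: K subfamily ancestors, then per-subfamily
    evolution along the species tree with Poisson duplication/loss.

    Diagnostic motif columns are disjoint across subfamilies; at each
    subfamily's ancestor they are set to a subfamily-specific residue and
    subsequently evolve at the reduced motif rate within that subfamily.
    Duplicates enter at the start of the branch they arise on; losses
    remove the copy and are logged against that branch.
    """
    rng = np.random.default_rng(seed)
    model = SubstModel(alpha=config.alpha, n_categories=config.n_categories)
    L = config.root_length
    site_rates = discrete_gamma_rates(config.alpha, config.n_categories)[
        rng.integers(0, config.n_categories, size=L)]
    root = rng.choice(N_AA, size=L, p=JTT_FREQS)

    body = L - config.tail_len
    motif_pool = rng.permutation(body)
    motif_columns = {
        sf: np.sort(motif_pool[i * config.n_motif_cols:(i + 1) * config.n_motif_cols])
        for i, sf in enumerate(config.subfamily_names)}

    tree = config.species_tree()
    events: list[SimEvent] = []
    proteins: list[SimProtein] = []
    gene_trees: dict[str, str] = {}

    def clade_label(node: dendropy.Node) -> str:
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        return leaves[0] if len(leaves) == 1 else "{" + ",".join(leaves) + "}"

    for sf in config.subfamily_names:
        anc = _evolve(root, config.b_sub, site_rates, model, rng)
        diag = rng.choice(N_AA, size=config.n_motif_cols, p=JTT_FREQS)
        anc[motif_columns[sf]] = diag
        sf_rates = site_rates.copy()
        sf_rates[motif_columns[sf]] *= config.motif_rate
        copy_counter = [0]

        def walk(node: dendropy.Node, copies: list[tuple[str, np.ndarray]],
                 subfam: str = sf, rates: np.ndarray = sf_rates) -> dict:
            """Returns {copy tree structure} while collecting tip proteins."""
            children_struct = {}
            if node.is_leaf():
                sp = node.taxon.label
                for cid, codes in copies:
                    seq = "".join(AMINO_ACIDS[c] for c in codes)
                    if subfam == config.tail_subfamily:
                        seq = seq[:body]
                    pid = f"{sp}|{subfam}|{cid}"
                    proteins.append(SimProtein(pid, sp, subfam, seq))
                    children_struct[cid] = pid
                return children_struct
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                label = clade_label(child)
                surviving: list[tuple[str, np.ndarray]] = []
                for cid, codes in copies:
                    if rng.poisson(config.lambda_loss * bl) > 0:
                        events.append(SimEvent(subfam, label, "loss", cid))
                        continue
                    lineage = [(cid, codes)]
                    for _ in range(rng.poisson(config.lambda_dup * bl)):
                        copy_counter[0] += 1
                        new_id = f"c{copy_counter[0]}"
                        events.append(SimEvent(subfam, label, "duplication", new_id))
                        lineage.append((new_id, codes))
                    for lid, lcodes in lineage:
                        surviving.append((lid, _evolve(lcodes, bl, rates, model, rng)))
                children_struct[label] = walk(child, surviving)
            return children_struct

        struct = walk(tree.seed_node, [("c0", anc)])
        gene_trees[sf] = json.dumps(struct)

    if not proteins:
        raise ValueError("empty family: all genes lost in all species")
    return FamilySimulation(config=config, seed=seed, proteins=proteins,
                            events=events, motif_columns=motif_columns,
                            site_rates=site_rates, gene_trees=gene_trees)


def simulate_alignment(tree: dendropy.Tree, nsites: int, model: SubstModel,
                       seed: int) -> MsAlignment:
    """Simulate a gapless protein alignment on a tree under the model.

    Per-site gamma category rates are drawn once at the root; each branch
    then evolves sites by sampling from the exact transition matrices.
    Used for likelihood and topology-test validation.
    """
    rng = np.random.default_rng(seed)
    site_rates = discrete_gamma_rates(model.alpha, model.n_categories)[
        rng.integers(0, model.n_categories, size=nsites)]
    if model.p_inv > 0:
        site_rates[rng.random(nsites) < model.p_inv] = 0.0
    root = rng.choice(N_AA, size=nsites, p=model.freqs)
    rows = []

    def walk(node: dendropy.Node, codes: np.ndarray) -> None:
        if node.is_leaf():
            rows.append((node.taxon.label,
                         "".join(AMINO_ACIDS[c] for c in codes)))
            return
        for child in node.child_nodes():
            walk(child, _evolve(codes, child.edge.length or 0.0,
                                site_rates, model, rng))

    walk(tree.seed_node, root)
    return MsAlignment(rows)


def simulate_decoy_family(config: SimConfig, seed: int, length: int | None = None,
                          name: str = "decoy") -> MsAlignment:
    """An unrelated protein family evolved on the same species tree.

    Independent root, no motif columns, no duplication/loss; used to build
    decoy profiles for reciprocal validation.
    """
    rng = np.random.default_rng(seed)
    model = SubstModel(alpha=config.alpha, n_categories=config.n_categories)
    L = length or (config.root_length - config.tail_len)
    site_rates = discrete_gamma_rates(config.alpha, config.n_categories)[
        rng.integers(0, config.n_categories, size=L)]
    root = rng.choice(N_AA, size=L, p=JTT_FREQS)
    tree = config.species_tree()
    rows = []

    def walk(node: dendropy.Node, codes: np.ndarray) -> None:
        if node.is_leaf():
            rows.append((f"{node.taxon.label}|{name}",
                         "".join(AMINO_ACIDS[c] for c in codes)))
            return
        for child in node.child_nodes():
            walk(child, _evolve(codes, child.edge.length or 0.0,
                                site_rates, model, rng))

    walk(tree.seed_node, root)
    return MsAlignment(rows, {rid: name for rid, _ in rows})


# ---------------------------------------------------------------------------
# genome emission
# ---------------------------------------------------------------------------

@dataclass
class TruthExon:
    gene_id: str
    species: str
    subfamily: str
    contig_id: str
    exon_index: int
    start: int
    end: int
    strand: str


@dataclass
class TruthTable:
    exons: list[TruthExon] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)  # gene_id -> aa seq
    presence: dict[tuple[str, str], bool] = field(default_factory=dict)
    loss_events: list[SimEvent] = field(default_factory=list)

    def genes(self) -> dict[str, list[TruthExon]]:
        out: dict[str, list[TruthExon]] = {}
        for e in self.exons:
            out.setdefault(e.gene_id, []).append(e)
        for exons in out.values():
            exons.sort(key=lambda e: e.exon_index)
        return out

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tspecies\tsubfamily\tcontig\texon\tstart\tend\tstrand\n")
            for e in self.exons:
                fh.write(f"{e.gene_id}\t{e.species}\t{e.subfamily}\t{e.contig_id}\t"
                         f"{e.exon_index}\t{e.start}\t{e.end}\t{e.strand}\n")


def _reverse_translate(seq: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_BY_AA[a][rng.integers(0, len(_CODONS_BY_AA[a]))]
                   for a in seq)


def _random_nuc(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _random_intron(n: int, rng: np.random.Generator) -> str:
    if n < 4:
        n = 4
    return "GT" + _random_nuc(n - 4, rng) + "AG"


def emit_genome(proteins: list[SimProtein], config: SimConfig,
                seed: int) -> tuple[list[NucContig], TruthTable]:
    """Reverse-translate tip proteins into exon/intron genes on contigs.

    Each protein is encoded with uniformly chosen synonymous codons, split
    into exons_per_gene exons at codon boundaries, and embedded at a
    random position and strand in a background-composition contig.  With
    probability fragmentation_rate the gene's exons are placed on separate
    contigs (no introns needed); otherwise the exons stay on one contig
    separated by GT..AG introns.  Decoy contigs without genes are added.
    Truth intervals are forward-strand 0-based half-open.
    """
    if not proteins:
        raise ValueError("no proteins to place")
    rng = np.random.default_rng(seed)
    contigs: list[NucContig] = []
    truth = TruthTable()
    ctg_counter = 0
    species = proteins[0].species

    def new_contig_id() -> str:
        nonlocal ctg_counter
        ctg_counter += 1
        return f"{species}_ctg{ctg_counter:03d}"

    def place(piece: str) -> tuple[str, int, int, str, list[int]]:
        """Embed a nucleotide piece in a fresh contig; returns contig id,
        forward-strand interval, strand, and offsets for sub-pieces."""
        left = int(rng.integers(*config.flank_len_range))
        right = int(rng.integers(*config.flank_len_range))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = piece if strand == "+" else reverse_complement(piece)
        contig_seq = _random_nuc(left, rng) + insert + _random_nuc(right, rng)
        cid = new_contig_id()
        contigs.append(NucContig(cid, contig_seq, species=species))
        return cid, left, left + len(piece), strand, []

    for prot in proteins:
        if prot.species != species:
            raise ValueError("emit_genome expects proteins from one species")
        cds = _reverse_translate(prot.seq, rng)
        n_aa = len(prot.seq)
        n_ex = config.exons_per_gene
        # codon-aligned exon cut points with a minimum exon size
        while True:
            cuts = np.sort(rng.integers(config.min_exon_aa,
                                        n_aa - config.min_exon_aa + 1,
                                        size=n_ex - 1))
            bounds = [0, *cuts.tolist(), n_aa]
            if all(bounds[i + 1] - bounds[i] >= config.min_exon_aa
                   for i in range(n_ex)):
                break
        exons_nt = [cds[3 * bounds[i]:3 * bounds[i + 1]] for i in range(n_ex)]
        gene_id = prot.id
        truth.proteins[gene_id] = prot.seq
        if rng.random() < config.fragmentation_rate:
            for i, ex in enumerate(exons_nt):
                cid, s, e, strand, _ = place(ex)
                truth.exons.append(TruthExon(gene_id, species, prot.subfamily,
                                             cid, i, s, e, strand))
        else:
            introns = [_random_intron(int(rng.integers(*config.intron_len_range)),
                                      rng) for _ in range(n_ex - 1)]
            gene = exons_nt[0]
            offsets = [0]
            for intr, ex in zip(introns, exons_nt[1:]):
                gene += intr
                offsets.append(len(gene))
                gene += ex
            cid, gs, ge, strand, _ = place(gene)
            for i, ex in enumerate(exons_nt):
                if strand == "+":
                    s = gs + offsets[i]
                    e = s + len(ex)
                else:
                    e = ge - offsets[i]
                    s = e - len(ex)
                truth.exons.append(TruthExon(gene_id, species, prot.subfamily,
                                             cid, i, s, e, strand))
    for _ in range(config.n_decoy_contigs):
        cid = new_contig_id()
        contigs.append(NucContig(cid, _random_nuc(config.decoy_contig_len, rng),
                                 species=species))
    return contigs, truth


def reconstruct_protein(contigs: list[NucContig], exons: list[TruthExon]) -> str:
    """Concatenate a gene's exon translations from its truth coordinates."""
    by_id = {c.id: c for c in contigs}
    parts = []
    for e in sorted(exons, key=lambda e: e.exon_index):
        span = by_id[e.contig_id].seq[e.start:e.end]
        if e.strand == "-":
            span = reverse_complement(span)
        parts.append(span)
    return translate("".join(parts), 1)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    overall_precision: float | None
    overall_recall: float | None
    presence_accuracy: float | None
    n_truth_genes: int
    n_accepted_calls: int


def _call_matches_truth(call, truth: TruthTable) -> bool:
    gene_exons = [e for e in truth.exons
                  if e.species == call.species and e.subfamily == call.subfamily]
    for h in call.hits:
        for e in gene_exons:
            if (h.contig_id == e.contig_id and h.nuc_start < e.end
                    and e.start < h.nuc_end):
                return True
    return False


def score_recovery(calls, truth: TruthTable,
                   predicted_presence: dict[tuple[str, str], str] | None = None
                   ) -> RecoveryMetrics:
    """Precision/recall of accepted calls and presence/absence accuracy.

    A call is correct iff its subfamily matches a planted gene in that
    species and at least one hit interval overlaps one of the gene's truth
    exons.  Presence accuracy compares a predicted species x subfamily
    state map ('present'/'absent') against the simulation's truth; unknown
    predicted cells are skipped.
    """
    accepted = [c for c in calls if c.status == "accepted"]
    truth_genes = truth.genes()
    subfamilies = sorted({e.subfamily for e in truth.exons} |
                         {c.subfamily for c in accepted})
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    n_correct_total = 0
    for sf in subfamilies:
        sf_calls = [c for c in accepted if c.subfamily == sf]
        correct = sum(1 for c in sf_calls if _call_matches_truth(c, truth))
        n_correct_total += correct
        precision[sf] = correct / len(sf_calls) if sf_calls else None
        sf_pairs = {(e.species, e.subfamily) for e in truth.exons
                    if e.subfamily == sf}
        if sf_pairs:
            recovered = sum(
                1 for (sp, _) in sf_pairs
                if any(c.species == sp and c.subfamily == sf
                       and _call_matches_truth(c, truth) for c in sf_calls))
            recall[sf] = recovered / len(sf_pairs)
        else:
            recall[sf] = None
    overall_precision = (n_correct_total / len(accepted)) if accepted else None
    truth_pairs = {(e.species, e.subfamily) for e in truth.exons}
    if truth_pairs:
        recovered = sum(1 for (sp, sf) in truth_pairs
                        if any(c.species == sp and c.subfamily == sf
                               and _call_matches_truth(c, truth)
                               for c in accepted))
        overall_recall = recovered / len(truth_pairs)
    else:
        overall_recall = None
    presence_accuracy = None
    if predicted_presence is not None and truth.presence:
        n_cells = n_ok = 0
        for key, truly_present in truth.presence.items():
            pred = predicted_presence.get(key)
            if pred is None or pred == "unknown":
                continue
            n_cells += 1
            n_ok += int((pred == "present") == truly_present)
        presence_accuracy = n_ok / n_cells if n_cells else None
    return RecoveryMetrics(precision=precision, recall=recall,
                           overall_precision=overall_precision,
                           overall_recall=overall_recall,
                           presence_accuracy=presence_accuracy,
                           n_truth_genes=len(truth_genes),
                           n_accepted_calls=len(accepted))


def fragment_classification_accuracy(hits, truth: TruthTable) -> float | None:
    """Accuracy of the best-E-value rule at the fragment level.

    For every (segment, region) column that overlaps a planted exon, the
    winning subfamily (minimum E-value over that column's hits) is
    compared with the exon's true subfamily.
    """
    by_col: dict[tuple[str, str], list] = {}
    for h in hits:
        by_col.setdefault((h.target_id, h.region), []).append(h)
    n = ok = 0
    for (target, region), col_hits in by_col.items():
        col_hits.sort(key=lambda h: (h.evalue, -h.bit_score))
        winner = col_hits[0]
        true_sf = None
        for e in truth.exons:
            if (e.contig_id == winner.contig_id and winner.nuc_start < e.end
                    and e.start < winner.nuc_end):
                true_sf = e.subfamily
                break
        if true_sf is None:
            continue
        n += 1
        ok += int(winner.subfamily == true_sf)
    return ok / n if n else None


def config_to_json(config: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)


def config_from_json(path: str) -> SimConfig:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("intron_len_range", "flank_len_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
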