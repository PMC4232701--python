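"""Synthetic family generation, genome emission, truth tables, recovery scoring."""

import dataclasses

import numpy as np
import pytest

from famscan.classify import OrthologyCall, Hit
from famscan.seqkit import translate
from famscan.synthdata import (SimConfig, TruthTable, default_regions,
                               emit_genome, fragment_classification_accuracy,
                               reconstruct_protein, score_recovery,
                               simulate_alignment, simulate_decoy_family,
                               simulate_family)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_subfamilies=1)
        with pytest.raises(ValueError):
            SimConfig(lambda_loss=-1.0)
        with pytest.raises(ValueError):
            SimConfig(n_motif_cols=100, n_subfamilies=5, root_length=300)

    def test_default_regions_exclude_tail(self, small_config):
        regions = default_regions(small_config)
        body = small_config.root_length - small_config.tail_len
        assert all(r.end_col <= body for r in regions)
        assert len({r.name for r in regions}) == 4


class TestSimulateFamily:
    def test_no_events_gives_k_genes_per_tip(self, small_config):
        fam = simulate_family(small_config, seed=1)
        species = sorted({p.species for p in fam.proteins})
        assert len(species) == 4
        for sp in species:
            subfams = [p.subfamily for p in fam.proteins if p.species == sp]
            assert sorted(subfams) == small_config.subfamily_names
        assert fam.events == []

    def test_tail_subfamily_is_shorter(self, small_config):
        fam = simulate_family(small_config, seed=1)
        body = small_config.root_length - small_config.tail_len
        for p in fam.proteins:
            expected = body if p.subfamily == small_config.tail_subfamily \
                else small_config.root_length
            assert len(p.seq) == expected

    def test_loss_events_consistent_with_missing_tips(self, small_config):
        """With duplications off, a subfamily is absent from a species iff
        a loss event lies on that species' root path."""
        cfg = dataclasses.replace(small_config, lambda_loss=2.0)
        fam = simulate_family(cfg, seed=7)
        presence = fam.presence()
        losses = [(e.subfamily, e.branch) for e in fam.events
                  if e.kind == "loss"]
        assert losses, "expected losses at this rate"
        for (sp, sf), present in presence.items():
            on_path = any(sf == lsf and (sp == br or
                                         (br.startswith("{") and sp in br))
                          for lsf, br in losses)
            assert present == (not on_path)

    def test_within_subfamily_identity_exceeds_between(self, small_config):
        """Pairwise identity within a subfamily exceeds identity between
        subfamilies in at least 99% of pairs."""
        fam = simulate_family(small_config, seed=3)
        by_sf = {}
        for p in fam.proteins:
            by_sf.setdefault(p.subfamily, []).append(p.seq[:150])

        def identity(a, b):
            return sum(x == y for x, y in zip(a, b)) / len(a)

        within = [identity(a, b) for seqs in by_sf.values()
                  for i, a in enumerate(seqs) for b in seqs[i + 1:]]
        sfs = sorted(by_sf)
        between = [identity(a, b) for i, s1 in enumerate(sfs)
                   for s2 in sfs[i + 1:]
                   for a in by_sf[s1][:3] for b in by_sf[s2][:3]]
        threshold = max(between)
        frac = np.mean([w > threshold for w in within])
        assert frac >= 0.99

    def test_pure_function_of_config_and_seed(self, small_config):
        f1 = simulate_family(small_config, seed=9)
        f2 = simulate_family(small_config, seed=9)
        assert [(p.id, p.seq) for p in f1.proteins] == \
            [(p.id, p.seq) for p in f2.proteins]
        f3 = simulate_family(small_config, seed=10)
        assert [p.seq for p in f3.proteins] != [p.seq for p in f1.proteins]

    def test_motif_columns_disjoint(self, small_config):
        fam = simulate_family(small_config, seed=2)
        seen = set()
        for cols in fam.motif_columns.values():
            as_set = set(cols.tolist())
            assert not (as_set & seen)
            seen |= as_set

    def test_decoy_family_unrelated(self, small_config):
        fam = simulate_family(small_config, seed=1)
        decoy = simulate_decoy_family(small_config, seed=99)
        fam_seq = fam.proteins[0].seq
        decoy_seq = decoy.rows[0][1]
        n = min(len(fam_seq), len(decoy_seq))
        ident = sum(a == b for a, b in zip(fam_seq[:n], decoy_seq[:n])) / n
        assert ident < 0.25  # near-random for unrelated sequences


class TestEmitGenome:
    def test_single_exon_interval_translates_to_protein(self, small_config):
        cfg = dataclasses.replace(small_config, exons_per_gene=1,
                                  fragmentation_rate=0.0)
        fam = simulate_family(cfg, seed=4)
        prots = [p for p in fam.proteins if p.species == "spA"]
        contigs, truth = emit_genome(prots, cfg, seed=8)
        by_id = {c.id: c for c in contigs}
        for gene_id, exons in truth.genes().items():
            assert len(exons) == 1
            e = exons[0]
            span = by_id[e.contig_id].seq[e.start:e.end]
            if e.strand == "-":
                from famscan.seqkit import reverse_complement
                span = reverse_complement(span)
            assert translate(span, 1) == truth.proteins[gene_id]

    def test_fragmented_genes_spread_over_contigs(self, small_config):
        cfg = dataclasses.replace(small_config, exons_per_gene=3,
                                  min_exon_aa=15, fragmentation_rate=1.0)
        fam = simulate_family(cfg, seed=4)
        prots = [p for p in fam.proteins if p.species == "spB"]
        contigs, truth = emit_genome(prots, cfg, seed=8)
        for gene_id, exons in truth.genes().items():
            assert len(exons) == 3
            assert len({e.contig_id for e in exons}) == 3

    def test_splice_reconstruction_oracle(self, small_config):
        """Concatenated exon translations equal the source protein for
        every planted gene, fragmented or not."""
        for frag in (0.0, 0.5, 1.0):
            cfg = dataclasses.replace(small_config, fragmentation_rate=frag)
            fam = simulate_family(cfg, seed=6)
            prots = [p for p in fam.proteins if p.species == "spC"]
            contigs, truth = emit_genome(prots, cfg, seed=16)
            for gene_id, exons in truth.genes().items():
                assert reconstruct_protein(contigs, exons) == \
                    truth.proteins[gene_id]

    def test_intron_boundaries_are_gt_ag(self, small_config):
        cfg = dataclasses.replace(small_config, fragmentation_rate=0.0,
                                  exons_per_gene=2)
        fam = simulate_family(cfg, seed=6)
        prots = [p for p in fam.proteins if p.species == "spD"][:2]
        contigs, truth = emit_genome(prots, cfg, seed=3)
        by_id = {c.id: c for c in contigs}
        from famscan.seqkit import reverse_complement
        for gene_id, exons in truth.genes().items():
            e0, e1 = exons
            contig = by_id[e0.contig_id].seq
            if e0.strand == "+":
                intron = contig[e0.end:e1.start]
            else:
                intron = reverse_complement(contig[e1.end:e0.start])
            assert intron.startswith("GT") and intron.endswith("AG")

    def test_deterministic(self, small_config):
        fam = simulate_family(small_config, seed=4)
        prots = [p for p in fam.proteins if p.species == "spA"]
        c1, t1 = emit_genome(prots, small_config, seed=8)
        c2, t2 = emit_genome(prots, small_config, seed=8)
        assert [(c.id, c.seq) for c in c1] == [(c.id, c.seq) for c in c2]
        assert t1.exons == t2.exons

    def test_empty_protein_list_rejected(self, small_config):
        with pytest.raises(ValueError):
            emit_genome([], small_config, seed=0)


def _fake_call(species, subfamily, exon, status="accepted"):
    hit = Hit(target_id="t", contig_id=exon.contig_id, species=species,
              region="TM1-4", subfamily=subfamily, bit_score=100.0,
              evalue=1e-30, nuc_start=exon.start, nuc_end=exon.end,
              strand=exon.strand, frame=1, aa_start=0, aa_end=10,
              reciprocal_ok=True)
    return OrthologyCall(gene_id=f"{species}|{subfamily}", species=species,
                         subfamily=subfamily, n_regions_hit=2,
                         reciprocal_ok=True, status=status, hits=[hit])


class TestScoreRecovery:
    @pytest.fixture
    def truth(self, small_config):
        fam = simulate_family(small_config, seed=4)
        truth = TruthTable()
        truth.presence = fam.presence()
        for sp in ("spA", "spB"):
            prots = [p for p in fam.proteins if p.species == sp]
            _, t = emit_genome(prots, small_config, seed=hash(sp) % 1000)
            truth.exons.extend(t.exons)
            truth.proteins.update(t.proteins)
        return truth

    def test_perfect_calls_score_one(self, truth):
        calls = []
        seen = set()
        for e in truth.exons:
            if (e.species, e.subfamily) not in seen:
                seen.add((e.species, e.subfamily))
                calls.append(_fake_call(e.species, e.subfamily, e))
        predicted = {(sp, sf): ("present" if v else "absent")
                     for (sp, sf), v in truth.presence.items()}
        m = score_recovery(calls, truth, predicted_presence=predicted)
        assert m.overall_precision == 1.0
        assert m.overall_recall == 1.0
        assert m.presence_accuracy == 1.0

    def test_zero_calls_degenerate(self, truth):
        m = score_recovery([], truth)
        assert m.overall_recall == 0.0
        assert m.overall_precision is None

    def test_shuffled_labels_collapse_precision(self, truth, small_config):
        """Randomly permuting subfamily labels leaves roughly 1/K of calls
        correct (the fixed points of the permutation)."""
        rng = np.random.default_rng(0)
        exons = [e for e in truth.exons]
        calls = []
        seen = set()
        for e in exons:
            if (e.species, e.subfamily) not in seen:
                seen.add((e.species, e.subfamily))
                wrong = small_config.subfamily_names[
                    int(rng.integers(small_config.n_subfamilies))]
                call = _fake_call(e.species, wrong, e)
                calls.append(call)
        m = score_recovery(calls, truth)
        assert m.overall_precision < 0.6  # ~1/K on average, K = 5

    def test_fragment_accuracy_ignores_background_hits(self, truth):
        e = truth.exons[0]
        on_exon = _fake_call(e.species, e.subfamily, e).hits[0]
        off_exon = Hit(target_id="bg", contig_id="nonexistent", species="x",
                       region="TM6", subfamily="S1", bit_score=10.0,
                       evalue=1e-6, nuc_start=0, nuc_end=30, strand="+",
                       frame=1, aa_start=0, aa_end=10)
        acc = fragment_classification_accuracy([on_exon, off_exon], truth)
        assert acc == 1.0
        assert fragment_classification_accuracy([off_exon], truth) is None


class TestDiscriminability:
    def test_accuracy_collapses_without_motifs_and_divergence(self, small_config):
        """With the diagnostic-motif rate multiplier at 1 (no motifs) and
        near-zero subfamily divergence, subfamily profiles become
        interchangeable and fragment classification accuracy falls toward
        chance (1/K), far below the default conditions."""
        import dataclasses
        from famscan.subfamlib import build_library
        from famscan.classify import scan_genome

        def run(cfg, seed):
            # leave-one-out: the scanned species is excluded from training
            fam = simulate_family(cfg, seed)
            aln = fam.alignment()
            training = aln.subset([i for i in aln.ids
                                   if not i.startswith("spA|")])
            lib = build_library(training, default_regions(cfg),
                                n_cal=150, seed=3)
            prots = [p for p in fam.proteins if p.species == "spA"]
            contigs, truth = emit_genome(prots, cfg, seed=seed + 1)
            hits = scan_genome(contigs, lib)
            return fragment_classification_accuracy(hits, truth)

        acc_default = run(small_config, seed=13)
        degraded_cfg = dataclasses.replace(small_config, n_motif_cols=0,
                                           motif_rate=1.0, b_sub=0.005)
        acc_degraded = run(degraded_cfg, seed=13)
        assert acc_default >= 0.9
        assert acc_degraded < 0.6
        assert acc_degraded < acc_default


class TestSimulateAlignment:
    def test_shape_and_determinism(self):
        import dendropy
        tree = dendropy.Tree.get(data="((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);",
                                 schema="newick")
        from famscan.phylo import SubstModel
        a1 = simulate_alignment(tree, 50, SubstModel(alpha=0.8), seed=1)
        a2 = simulate_alignment(tree, 50, SubstModel(alpha=0.8), seed=1)
        assert a1.rows == a2.rows
        assert a1.ncols == 50 and a1.nrows == 4

    def test_longer_branches_accumulate_more_change(self):
        import dendropy
        from famscan.phylo import SubstModel
        short = dendropy.Tree.get(data="(A:0.01,B:0.01);", schema="newick")
        long_ = dendropy.Tree.get(data="(A:1.5,B:1.5);", schema="newick")
        m = SubstModel()
        a_short = simulate_alignment(short, 300, m, seed=2)
        a_long = simulate_alignment(long_, 300, m, seed=2)

        def ident(aln):
            (_, s1), (_, s2) = aln.rows
            return sum(a == b for a, b in zip(s1, s2)) / len(s1)

        assert ident(a_short) > 0.9 > 0.6 > ident(a_long)
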