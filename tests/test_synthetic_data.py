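"""The barrier-model generator: placement arithmetic, determinism, noise."""

import numpy as np
import pytest

from nucbarrier.classify import GenomeAnnotation
from nucbarrier.simulate import (
    BarrierClassSpec,
    GroundTruth,
    PlacementError,
    SimulationConfig,
    emit_dnase_tags,
    emit_mnase_fragments,
    fragments_to_tags,
    simulate,
    true_nucleosome_map,
    write_simulation,
)
from nucbarrier.types import GenomicInterval


def one_barrier_truth(start=900, end=1000, klass="intergenic"):
    return GroundTruth(
        barriers=[GenomicInterval("chr1", start, end, name=klass)],
        barrier_classes=[klass],
        class_linker={klass: 0},
        class_spacing={klass: 147},
    )


def bare_config(linker=0, sigma0=0.0, dsigma=0.0, n_nucs=2, **kw):
    defaults = dict(
        chrom_sizes={"chr1": 10_000},
        minus1_occupancy=0.0,
        background_dyads_per_kb=0.0,
        digestion_sigma=0.0,
        center_noise=0.0,
        seed=0,
    )
    defaults.update(kw)
    cfg = SimulationConfig(**defaults)
    cfg.classes = {
        "intergenic": BarrierClassSpec(1, 100, 100, linker=linker, sigma0=sigma0, dsigma=dsigma, n_nucs=n_nucs)
    }
    return cfg


class TestDyadPlacement:
    def test_zero_linker_dyads_abut_the_barrier(self):
        truth = true_nucleosome_map(one_barrier_truth(), bare_config())
        right = sorted(d.pos for d in truth.dyads if d.side == "R")
        left = sorted(d.pos for d in truth.dyads if d.side == "L")
        assert right == [1073, 1220]  # edge + 73, then + core
        assert left == [679, 826]  # edge - 74, then - core

    def test_linker_35_spacing_182(self):
        truth = true_nucleosome_map(one_barrier_truth(), bare_config(linker=35, n_nucs=3))
        right = sorted(d.pos for d in truth.dyads if d.side == "R")
        assert np.all(np.diff(right) == 182)

    def test_jitter_sd_matches_sigma0(self):
        # many independent single-nucleosome arrays; deviation of dyad_1 ~ N(0, 9)
        cfg = bare_config(sigma0=9.0, n_nucs=1, seed=5)
        deviations = []
        for rep in range(400):
            cfg.seed = rep
            truth = true_nucleosome_map(one_barrier_truth(), cfg)
            for d in truth.dyads:
                expected = 1073 if d.side == "R" else 826
                deviations.append(d.pos - expected)
        sd = np.std(deviations)
        assert abs(sd - 9.0) < 1.0
        assert abs(np.mean(deviations)) < 1.0

    def test_minus1_dyad_at_barrier_center(self):
        cfg = bare_config(minus1_occupancy=0.3)
        truth = true_nucleosome_map(one_barrier_truth(), cfg)
        center = [d for d in truth.dyads if d.side == "C"]
        assert len(center) == 1
        assert center[0].pos == 950 and center[0].weight == 0.3


class TestFragments:
    def test_noiseless_fragments_cover_exact_core(self):
        cfg = bare_config(n_nucs=1, depth=30.0)
        truth = true_nucleosome_map(one_barrier_truth(), cfg)
        frags = [f for f in emit_mnase_fragments(truth, cfg) if f.start >= 1000]
        assert frags  # right-side dyad at 1073
        assert all((f.start, f.end) == (1000, 1147) for f in frags)

    def test_poisson_depth_mean(self):
        cfg = bare_config(n_nucs=5, depth=50.0, chrom_sizes={"chr1": 20_000})
        truth = true_nucleosome_map(one_barrier_truth(), cfg)
        n_dyads = len(truth.dyads)
        frags = emit_mnase_fragments(truth, cfg)
        expected = 50.0 * n_dyads
        assert abs(len(frags) - expected) < 4 * np.sqrt(expected)

    def test_fragment_length_mean_near_core(self):
        cfg = bare_config(n_nucs=5, depth=250.0, digestion_sigma=10.0, chrom_sizes={"chr1": 20_000})
        truth = true_nucleosome_map(one_barrier_truth(), cfg)
        lengths = np.array([f.length for f in emit_mnase_fragments(truth, cfg)])
        assert lengths.size >= 2000
        assert abs(lengths.mean() - 147.0) < 1.0
        assert lengths.min() >= 100 and lengths.max() <= 250

    def test_tags_are_both_fragment_ends(self):
        cfg = bare_config(n_nucs=1, depth=10.0)
        truth = true_nucleosome_map(one_barrier_truth(), cfg)
        frags = emit_mnase_fragments(truth, cfg)
        tags = fragments_to_tags(frags)
        assert len(tags) == 2 * len(frags)
        fwd = {t.pos5 for t in tags if t.strand == "+"}
        rev = {t.pos5 for t in tags if t.strand == "-"}
        assert fwd == {f.start for f in frags}
        assert rev == {f.end - 1 for f in frags}


class TestDnase:
    def test_zero_background_all_tags_in_barriers(self):
        cfg = bare_config(dnase_rate_in=0.5, dnase_rate_bg=0.0)
        truth = one_barrier_truth()
        tags = emit_dnase_tags(truth, cfg)
        assert tags and all(900 <= t.pos5 < 1000 for t in tags)

    def test_rate_ratio_concentrates_tags(self):
        # barriers cover 20% of the genome at a 50:1 cut-rate ratio ->
        # expected in-barrier share (0.2*50 + 0.2) / (0.2*50 + 1) ~ 0.93
        cfg = bare_config(chrom_sizes={"chr1": 10_000}, dnase_rate_in=0.5, dnase_rate_bg=0.01)
        truth = GroundTruth(
            barriers=[GenomicInterval("chr1", 1000, 2000), GenomicInterval("chr1", 5000, 6000)],
            barrier_classes=["intergenic", "intergenic"],
        )
        tags = emit_dnase_tags(truth, cfg)
        inside = sum(1000 <= t.pos5 < 2000 or 5000 <= t.pos5 < 6000 for t in tags)
        assert inside / len(tags) >= 0.9


class TestGenomeLayout:
    def test_determinism_same_seed(self):
        a = simulate(SimulationConfig(seed=11))
        b = simulate(SimulationConfig(seed=11))
        assert a.fragments == b.fragments
        assert a.dnase_tags == b.dnase_tags
        assert a.truth.barriers == b.truth.barriers

    def test_different_seed_differs(self):
        a = simulate(SimulationConfig(seed=11))
        b = simulate(SimulationConfig(seed=12))
        assert a.fragments != b.fragments

    def test_barrier_categories_match_labels(self, default_sim):
        ann = GenomeAnnotation(default_sim.genes)
        for barrier, klass in zip(default_sim.truth.barriers, default_sim.truth.barrier_classes):
            assert ann.category_of(barrier.chrom, barrier.midpoint) == klass

    def test_adjacent_dyads_spaced_core_plus_linker(self, recovery_sim):
        # zero jitter: consecutive same-side dyads in one array differ by spacing
        truth = recovery_sim.truth
        spacing = truth.class_spacing
        by_array = {}
        for d in truth.dyads:
            if d.array_index >= 1:
                by_array.setdefault((d.barrier_id, d.side), []).append((d.array_index, d.pos))
        for (bid, _side), items in by_array.items():
            items.sort()
            klass = truth.barrier_classes[bid]
            gaps = np.abs(np.diff([pos for _, pos in items]))
            assert np.all(gaps == spacing[klass])

    def test_overfull_genome_raises(self):
        cfg = SimulationConfig(chrom_sizes={"chr1": 50_000})
        with pytest.raises(PlacementError):
            simulate(cfg)

    def test_too_many_attached_barriers_raises(self):
        cfg = SimulationConfig(n_genes=3)
        with pytest.raises(PlacementError):
            simulate(cfg)

    def test_write_simulation_outputs_parse_back(self, tmp_path, default_sim):
        from nucbarrier import io as nbio

        paths = write_simulation(default_sim, str(tmp_path))
        assert nbio.read_chrom_sizes(paths["sizes"]) == default_sim.sizes
        frags = nbio.read_fragments(paths["fragments"])
        assert frags == default_sim.fragments
        tags = nbio.read_tags(paths["dnase_tags"])
        assert len(tags) == len(default_sim.dnase_tags)
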