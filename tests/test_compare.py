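"""Tissue merging / differential classification and RPKM quantification."""

import numpy as np
import pytest

import plastedit as pe
from plastedit.pileup import Pileup

from conftest import edit_site_at, make_header, make_read


def _pileup_with(genome, at: dict[int, dict[str, int]]) -> Pileup:
    counts = np.zeros((len(genome), 4), dtype=np.int64)
    for pos, bases in at.items():
        for base, n in bases.items():
            counts[pos - 1, "ACGT".index(base)] = n
    return Pileup(genome, counts)


@pytest.fixture()
def c_genome():
    seq = list("ATGA" * 30)
    seq[49] = "C"  # lone C at position 50
    return pe.ReferenceGenome("m", "".join(seq))


def _merge_single_site(c_genome, leaf_eff, flower_eff, depth=100, threshold=0.20):
    """Both tissues covered at `depth`; site called wherever thresholds pass."""
    calls = {}
    pileups = {}
    for tissue, eff in (("leaf", leaf_eff), ("flower", flower_eff)):
        edited = round(eff * depth)
        pileups[tissue] = _pileup_with(
            c_genome, {50: {"C": depth - edited, "T": edited}}
        )
        called = depth >= 10 and edited >= 2 and edited / depth >= 0.05
        calls[tissue] = [edit_site_at(50, edited=edited, depth=depth)] if called else []
    return pe.merge_tissues(calls, pileups, pe.CallParams(), threshold)


class TestMergeTissues:
    def test_trnm_style_upregulation(self, c_genome):
        # 93% in leaf vs 64% in flower: up by 29 percentage points
        (rec,) = _merge_single_site(c_genome, 0.93, 0.64)
        assert rec.status == "common"
        assert rec.delta == pytest.approx(0.29)
        assert rec.differential_flag and rec.direction == "up"

    def test_equal_efficiencies_not_differential(self, c_genome):
        (rec,) = _merge_single_site(c_genome, 0.5, 0.5)
        assert rec.delta == pytest.approx(0.0)
        assert not rec.differential_flag and rec.direction == "none"

    def test_downregulated_direction(self, c_genome):
        (rec,) = _merge_single_site(c_genome, 0.30, 0.62)
        assert rec.direction == "down" and rec.delta == pytest.approx(-0.32)

    def test_subthreshold_efficiency_recorded_not_absent(self, c_genome):
        # 3% in flower is below the calling floor but must appear as 0.03
        (rec,) = _merge_single_site(c_genome, 0.40, 0.03)
        assert rec.called["leaf"] and not rec.called["flower"]
        assert rec.efficiency["flower"] == pytest.approx(0.03)
        assert rec.status == "tissue_specific:leaf"
        assert rec.differential_flag and rec.direction == "up"

    def test_undercovered_other_tissue_is_unknown(self, c_genome):
        calls = {
            "leaf": [edit_site_at(50, edited=40, depth=100)],
            "flower": [],
        }
        pileups = {
            "leaf": _pileup_with(c_genome, {50: {"C": 60, "T": 40}}),
            "flower": _pileup_with(c_genome, {50: {"C": 5}}),  # depth 5 < 10
        }
        (rec,) = pe.merge_tissues(calls, pileups, pe.CallParams())
        assert rec.status == "unknown"
        assert rec.efficiency["flower"] is None
        assert rec.low_coverage and not rec.differential_flag
        assert rec.delta is None

    def test_threshold_monotonicity(self, c_genome):
        flagged = []
        for thr in (0.0, 0.1, 0.2, 0.35):
            (rec,) = _merge_single_site(c_genome, 0.80, 0.55, threshold=thr)
            flagged.append(rec.differential_flag)
        # 0.25-point gap: differential until the threshold passes it
        assert flagged == [True, True, True, False]
        # at threshold 0 any inequality is differential
        (rec,) = _merge_single_site(c_genome, 0.51, 0.50, threshold=0.0)
        assert rec.differential_flag

    def test_union_keyed_by_position_type_and_orientation(self, c_genome):
        # sites unique to each tissue both appear in the merged set
        seq = list(c_genome.sequence)
        seq[69] = "C"
        genome = pe.ReferenceGenome("m2", "".join(seq))
        pu_leaf = _pileup_with(genome, {50: {"C": 50, "T": 50}, 70: {"C": 100}})
        pu_flower = _pileup_with(genome, {50: {"C": 100}, 70: {"C": 50, "T": 50}})
        calls = {
            "leaf": [edit_site_at(50)],
            "flower": [edit_site_at(70)],
        }
        recs = pe.merge_tissues(calls, {"leaf": pu_leaf, "flower": pu_flower})
        assert [r.position for r in recs] == [50, 70]
        assert recs[0].status == "tissue_specific:leaf"
        assert recs[1].status == "tissue_specific:flower"

    def test_planted_tissue_specific_site_recovered(self, demo_dataset, demo_calls):
        truth = demo_dataset.truth
        specific = [t for t in truth if t.true_efficiency["flower"] == 0.0
                    and t.true_efficiency["leaf"] >= 0.25]
        assert specific
        recs = pe.merge_tissues(
            {t: demo_calls[t]["sites"] for t in ("leaf", "flower")},
            {t: demo_calls[t]["pileup"] for t in ("leaf", "flower")},
        )
        by_pos = {r.position: r for r in recs}
        for t in specific:
            rec = by_pos[t.position]
            assert rec.status == "tissue_specific:leaf"
            assert rec.delta == pytest.approx(t.true_efficiency["leaf"], abs=0.12)


class TestRpkm:
    def _uniform_reads(self, genome, n, length=50, seed=0):
        header = make_header(genome)
        rng = np.random.default_rng(seed)
        starts = rng.integers(1, len(genome) - length + 1, size=n)
        return [
            make_read(header, f"r{i}", genome.sequence[s - 1 : s - 1 + length], s, nm=0)
            for i, s in enumerate(starts)
        ]

    def test_formula_identity(self):
        """1000 bp gene, 10 midpoint reads, library forced to one million:
        RPKM = 10 / 1 kb / 1 M = 10."""
        genome = pe.ReferenceGenome("r", "ACGT" * 500)
        gene = pe.FeatureRecord("g", "CDS", [(501, 1500)], "+")
        header = make_header(genome)
        reads = [
            make_read(header, f"r{i}", genome.sequence[899:949], 900, nm=0)
            for i in range(10)
        ]
        (rec,) = pe.compute_rpkm(reads, [gene], library_size=1_000_000)
        assert rec.count == 10
        assert rec.rpkm == pytest.approx(10.0)

    def test_zero_count_gene_and_undefined_ratio(self):
        genome = pe.ReferenceGenome("r", "ACGT" * 500)
        genes = [
            pe.FeatureRecord("hit", "CDS", [(1, 300)], "+"),
            pe.FeatureRecord("empty", "CDS", [(1500, 1800)], "+"),
        ]
        header = make_header(genome)
        reads = [make_read(header, "r0", genome.sequence[:50], 1, nm=0)]
        table = pe.expression_table({"leaf": reads, "flower": reads}, genes)
        empty = table[table["gene"] == "empty"].iloc[0]
        assert empty["count_leaf"] == 0 and empty["rpkm_leaf"] == 0.0
        assert np.isnan(empty["ratio"])

    def test_zero_library_raises(self):
        genome = pe.ReferenceGenome("r", "ACGT" * 100)
        gene = pe.FeatureRecord("g", "CDS", [(1, 300)], "+")
        with pytest.raises(pe.DataError):
            pe.compute_rpkm([], [gene])

    def test_duplicating_every_read_preserves_rpkm(self):
        genome = pe.ReferenceGenome("r", "ACGT" * 1000)
        genes = [pe.FeatureRecord("g1", "CDS", [(101, 700)], "+"),
                 pe.FeatureRecord("g2", "CDS", [(2001, 3200)], "-")]
        reads = self._uniform_reads(genome, 2000)
        once = {r.gene: r.rpkm for r in pe.compute_rpkm(reads, genes)}
        twice = {r.gene: r.rpkm for r in pe.compute_rpkm(reads + reads, genes)}
        for g in once:
            assert twice[g] == pytest.approx(once[g])

    def test_uniform_coverage_gives_equal_rpkm(self, demo_dataset, demo_calls):
        genes = [f for f in demo_dataset.features if f.feature_class == "CDS"]
        recs = pe.compute_rpkm(demo_calls["leaf"]["reads"], genes)
        rpkms = np.array([r.rpkm for r in recs])
        # uniform read placement: all genes share RPKM ~ 1e9 / genome length
        assert np.all(np.abs(rpkms / rpkms.mean() - 1) < 0.15)

    def test_expression_multiplier_doubles_rpkm(self, tmp_path):
        from conftest import tiny_config

        cfg = tiny_config(
            n_edits=0, mean_coverage=300.0,
            expression_multipliers={"g02": 2.0},
        )
        genome, features = pe.generate_genome(cfg)
        sam = pe.simulate_reads(genome, [], cfg, "leaf", tmp_path / "m.sam",
                                features=features)
        reads = pe.read_sam(sam)
        genes = [f for f in features if f.feature_class == "CDS"]
        recs = {r.gene: r.rpkm for r in pe.compute_rpkm(reads, genes)}
        assert recs["g02"] / recs["g01"] == pytest.approx(2.0, rel=0.15)


def test_accounting_identity_on_synthetic_run(demo_calls):
    leaf = {s.key for s in demo_calls["leaf"]["sites"]}
    flower = {s.key for s in demo_calls["flower"]["sites"]}
    recs = pe.merge_tissues(
        {t: demo_calls[t]["sites"] for t in ("leaf", "flower")},
        {t: demo_calls[t]["pileup"] for t in ("leaf", "flower")},
    )
    assert len(recs) == len(leaf | flower)
    assert len(leaf) + len(flower) - len(leaf & flower) == len(recs)
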