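"""Read pipeline: demultiplexing, UMI collapse, translation, classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

import slisy
from slisy.reads import (
    CODON_TO_AA,
    PipelineError,
    _translate_segments,
    default_layout,
    translate_nt,
)


def make_read(barcode="ACGTAC", umi="A" * 14, segments=("ATG",), cid="c0"):
    return slisy.SegmentRead(
        cluster_id=cid, sample_index=barcode, umi=umi, segments=tuple(segments)
    )


class TestDemultiplex:
    INDEX = {"ACGTAC": "input", "TGCATG": "trbc2"}

    def test_exact_match_assigned(self):
        r = make_read("ACGTAC")
        out = slisy.demultiplex([r], self.INDEX)
        assert out.by_sample["input"] == [r]
        assert out.n_discarded == 0

    def test_distant_barcode_discarded(self):
        out = slisy.demultiplex([make_read("GGGGGG")], self.INDEX, max_mismatch=1)
        assert out.n_discarded == 1

    def test_one_mismatch_recovered_with_tolerance(self):
        r = make_read("ACGTAA")
        assert slisy.demultiplex([r], self.INDEX, max_mismatch=0).n_discarded == 1
        out = slisy.demultiplex([r], self.INDEX, max_mismatch=1)
        assert out.by_sample["input"] == [r]

    def test_duplicate_barcode_rejected(self):
        with pytest.raises(PipelineError):
            slisy.demultiplex([], [("ACGTAC", "a"), ("ACGTAC", "b")])

    def test_conservation_over_random_barcodes(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        reads = [
            make_read("".join(rng.choice(bases, 6)), cid=f"c{i}")
            for i in range(300)
        ]
        out = slisy.demultiplex(reads, self.INDEX)
        assert sum(map(len, out.by_sample.values())) + out.n_discarded == 300


class TestCollapseUmis:
    def test_identical_reads_collapse_to_one_molecule(self):
        reads = [make_read(umi="ACGTACGTACGTAC", cid=f"c{i}") for i in range(5)]
        mols = slisy.collapse_umis(reads)
        assert len(mols) == 1
        assert mols[0].n_reads == 5

    def test_same_umi_different_sequence_stay_distinct(self):
        a = make_read(umi="ACGTACGTACGTAC", segments=("ATG",))
        b = make_read(umi="ACGTACGTACGTAC", segments=("TTG",))
        assert len(slisy.collapse_umis([a, b])) == 2

    def test_collapse_recovers_simulated_molecule_count(self, toy8):
        rng = np.random.default_rng(42)
        n_mol = 200
        table_reads = []
        for i in range(n_mol):
            umi = "".join(rng.choice(list("ACGT"), 14))
            for _ in range(rng.geometric(1 / 3.0)):
                table_reads.append(make_read(umi=umi, cid=f"c{i}"))
        assert len(slisy.collapse_umis(table_reads)) == n_mol


class TestTranslate:
    def test_matches_biopython_on_random_orfs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            nt = "".join(rng.choice(list("ACGT"), 30))
            mine = translate_nt(nt)
            ref = str(Seq(nt).translate())
            if "*" in ref:
                assert mine is None
            else:
                assert mine == ref

    def test_stop_codon_is_untranslatable(self, toy8):
        layout = default_layout(toy8, n_segments=1)
        assert _translate_segments(("TAA" * len(toy8.cdr_positions),), layout) is None

    def test_non_acgt_base_is_untranslatable(self, toy8):
        layout = default_layout(toy8, n_segments=1)
        nt = "N" + "ATG" * len(toy8.cdr_positions)
        assert _translate_segments((nt[: 3 * len(toy8.cdr_positions)],), layout) is None

    def test_parent_windows_translate_to_parent_peptide(self, toy8):
        layout = default_layout(toy8)
        nt = slisy.reverse_translate(toy8.window_peptide())
        bounds = [(3 * a, 3 * b) for a, b in layout.windows]
        segments = tuple(nt[a:b] for a, b in bounds)
        read = make_read(segments=segments)
        assert slisy.assemble_translate(read, layout) == toy8.window_peptide()

    def test_codon_map_covers_the_standard_code(self):
        # 61 sense codons + 3 stops
        assert len(CODON_TO_AA) == 64
        assert sum(1 for aa in CODON_TO_AA.values() if aa == "*") == 3


def classify_oracle(peptide, design):
    """Exhaustive scan over {backbone} + all enumerated clones."""
    backbone = design.window_peptide()
    dist_backbone = sum(a != b for a, b in zip(peptide, backbone))
    if dist_backbone == 0:
        return "parent"
    if dist_backbone == 1:
        for clone in design.variants:
            if design.window_peptide(clone.aa_sequence) == peptide:
                return clone.clone_id
    return "unassigned"


class TestClassify:
    def test_backbone_peptide_is_parent(self, toy8):
        a = slisy.classify(toy8.window_peptide(), toy8)
        assert a.assigned == "parent" and a.n_alterations == 0

    def test_enumerated_clone_recovered(self, toy8):
        clone = toy8.variants[11]
        a = slisy.classify(toy8.window_peptide(clone.aa_sequence), toy8)
        assert a.assigned == clone.clone_id and a.n_alterations == 1

    def test_double_mutant_unassigned(self, toy8):
        pep = list(toy8.window_peptide())
        for i in (0, 1):
            pep[i] = "W" if pep[i] != "W" else "Y"
        a = slisy.classify("".join(pep), toy8)
        assert a.assigned == "unassigned" and a.n_alterations == 2

    def test_length_mismatch_raises(self, toy8):
        with pytest.raises(PipelineError):
            slisy.classify("A", toy8)

    @pytest.mark.parametrize("n_sites,seed", [(4, 0), (7, 1), (10, 2)])
    def test_agrees_with_exhaustive_oracle(self, n_sites, seed):
        design = slisy.toy_design(n_sites=n_sites, seed=seed)
        backbone = design.window_peptide()
        rng = np.random.default_rng(seed)
        aas = list(slisy.CANONICAL_AA)
        for _ in range(1000 // 3):
            pep = list(backbone)
            for pos in rng.choice(len(pep), size=rng.integers(0, 4), replace=False):
                pep[pos] = aas[rng.integers(0, 20)]
            peptide = "".join(pep)
            got = slisy.classify(peptide, design).assigned
            assert got == classify_oracle(peptide, design)


class TestTally:
    def test_empty_assignments_give_zero_table(self, toy8):
        roles = {"input": "input_library", "trbc2": "trbc2_bound",
                 "trbc1": "trbc1_bound"}
        table = slisy.tally({s: [] for s in roles}, toy8, roles)
        assert (table.counts.values == 0).all()
        assert set(table.counts.index) == {c.clone_id for c in toy8.clones}

    def test_column_sums_equal_assigned_molecules(self, toy8):
        truth = slisy.PanningTruth.uniform_with_hot_clone(
            toy8, toy8.variants[0].clone_id
        )
        cfg = slisy.SimConfig(depth=2000, error_rate=0.01, seed=5)
        table = slisy.simulate_panning(truth, cfg, design=toy8)
        reads = slisy.emit_reads(table, toy8, cfg)
        index_map = {b: s for b, s in
                     zip(("ACGTAC", "TGCATG", "GTACGT"), table.counts.columns)}
        out, qc = slisy.count_reads(reads, toy8, index_map, cfg.roles)
        for sample, col in out.counts.items():
            assert col.sum() == qc.per_sample[sample]["assigned"]
            s = qc.per_sample[sample]
            assert s["assigned"] + s["unassigned"] + s["untranslatable"] == \
                s["molecules"]


def test_read_tsv_round_trip(tmp_path, toy8):
    truth = slisy.PanningTruth.uniform_with_hot_clone(toy8, toy8.variants[2].clone_id)
    cfg = slisy.SimConfig(depth=300, error_rate=0.0, umi_dup_mean=1.0, seed=9)
    table = slisy.simulate_panning(truth, cfg, design=toy8)
    reads = slisy.emit_reads(table, toy8, cfg)
    path = tmp_path / "reads.tsv"
    from slisy.reads import read_tsv, write_tsv

    write_tsv(reads, path)
    back = read_tsv(path)
    assert back == reads
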