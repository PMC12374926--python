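import numpy as np
import pandas as pd
import pytest

from immunosite.errors import ValidationError
from immunosite.io_formats import read_cell_table, read_contig_table
from immunosite.repertoire import (
    Clonotype,
    ExpansionBinning,
    Repertoire,
    assemble_clonotypes,
    bin_expansion,
    build_repertoire,
    expanded_composition,
)

from conftest import contig_frame, contig_row, make_clone, make_repertoire


def cells_frame(rows):
    return pd.DataFrame(rows, columns=["barcode", "sample_id", "patient_id", "tissue",
                                       "replicate", "cell_type", "lineage"])


class TestClonotype:
    def test_identity_on_nucleotides_only(self):
        a = Clonotype("AAA", "CCC", cdr3a_aa="X", cdr3b_aa="Y")
        b = Clonotype("AAA", "CCC", cdr3a_aa="Q", cdr3b_aa="R")
        assert a == b and hash(a) == hash(b)
        assert a != Clonotype("AAA", "CCG")


class TestAssemble:
    def test_simple_pair(self):
        contigs = contig_frame([
            contig_row("bc1", "TRA", cdr3_nt="TGTGCA", cdr3="CAF"),
            contig_row("bc1", "TRB", cdr3_nt="TGTGGC", cdr3="CBF"),
        ])
        result = assemble_clonotypes(contigs)
        assert result["bc1"] == Clonotype("TGTGCA", "TGTGGC")
        assert result["bc1"].cdr3a_aa == "CAF"

    def test_umi_dominant_alpha_selected(self):
        contigs = contig_frame([
            contig_row("bc1", "TRA", cdr3_nt="AAAAAA", umis=7),
            contig_row("bc1", "TRA", cdr3_nt="CCCCCC", umis=3),
            contig_row("bc1", "TRB", cdr3_nt="GGGGGG", umis=5),
        ])
        assert assemble_clonotypes(contigs)["bc1"].cdr3a_nt == "AAAAAA"

    def test_tie_break_reads_then_lexicographic(self):
        contigs = contig_frame([
            contig_row("bc1", "TRA", cdr3_nt="CCC", umis=5, reads=10),
            contig_row("bc1", "TRA", cdr3_nt="AAA", umis=5, reads=10),
            contig_row("bc1", "TRA", cdr3_nt="GGG", umis=5, reads=90),
            contig_row("bc1", "TRB", cdr3_nt="TTT", umis=5),
        ])
        assert assemble_clonotypes(contigs)["bc1"].cdr3a_nt == "GGG"
        no_reads = contig_frame([
            contig_row("bc1", "TRA", cdr3_nt="CCC", umis=5, reads=10),
            contig_row("bc1", "TRA", cdr3_nt="AAA", umis=5, reads=10),
            contig_row("bc1", "TRB", cdr3_nt="TTT", umis=5),
        ])
        assert assemble_clonotypes(no_reads)["bc1"].cdr3a_nt == "AAA"

    def test_beta_only_maps_to_none(self):
        contigs = contig_frame([contig_row("bc1", "TRB")])
        assert assemble_clonotypes(contigs)["bc1"] is None

    def test_beta_only_mode(self):
        contigs = contig_frame([contig_row("bc1", "TRB", cdr3_nt="GGG")])
        clone = assemble_clonotypes(contigs, beta_only=True)["bc1"]
        assert clone == Clonotype("", "GGG")

    def test_nonproductive_and_low_confidence_ignored(self):
        contigs = contig_frame([
            contig_row("bc1", "TRA", productive=False),
            contig_row("bc1", "TRA", high_confidence=False),
            contig_row("bc1", "TRB"),
        ])
        assert assemble_clonotypes(contigs)["bc1"] is None

    def test_row_permutation_invariant(self):
        rows = [
            contig_row("bc1", "TRA", cdr3_nt="AAA", umis=5),
            contig_row("bc1", "TRA", cdr3_nt="CCC", umis=5),
            contig_row("bc1", "TRB", cdr3_nt="GGG", umis=2),
            contig_row("bc2", "TRA", cdr3_nt="TTT", umis=1),
            contig_row("bc2", "TRB", cdr3_nt="ATA", umis=1),
        ]
        base = assemble_clonotypes(contig_frame(rows))
        rng = np.random.default_rng(1)
        for _ in range(5):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            assert assemble_clonotypes(contig_frame(perm)) == base

    def test_empty_input(self):
        assert assemble_clonotypes(contig_frame([]).reindex(columns=[
            "barcode", "chain", "cdr3", "cdr3_nt", "umis", "productive",
            "reads", "v_gene", "j_gene", "high_confidence"])) == {}


class TestBuildRepertoire:
    def test_tally(self):
        x, y, z = make_clone("x"), make_clone("y"), make_clone("z")
        mapping = {f"b{i}": c for i, c in enumerate([x, x, x, y, z])}
        cells = cells_frame([(f"b{i}", "s1", "p1", "tumor", 1, "T", "CD8") for i in range(5)])
        rep = build_repertoire(mapping, cells, "s1")
        assert rep.clone_counts == {x: 3, y: 1, z: 1}
        assert rep.pool_size == 5

    def test_empty_sample(self):
        cells = cells_frame([("b0", "s1", "p1", "blood", 1, "T", "CD8")])
        rep = build_repertoire({"b0": None}, cells, "s1")
        assert rep.pool_size == 0

    def test_unknown_sample_raises(self):
        cells = cells_frame([("b0", "s1", "p1", "blood", 1, "T", "CD8")])
        with pytest.raises(LookupError):
            build_repertoire({}, cells, "nope")

    def test_synthetic_sample_matches_planted_multiset(self, study):
        truth = study.ground_truth
        sid = "P01_tumor1"
        contigs = read_contig_table(study.sample_dirs[sid] / "contigs.csv")
        cells = read_cell_table(study.cells_path)
        rep = build_repertoire(assemble_clonotypes(contigs), cells, sid)
        observed = {c.key: n for c, n in rep.clone_counts.items()}
        assert observed == truth["clone_counts"][sid]


class TestBinning:
    def test_worked_example(self):
        # pool of 1000: counts 1/5/15/30/60 -> unique/small/medium/large/hyper
        counts = {"a": 1, "b": 5, "c": 15, "d": 30, "e": 60, "filler": 889}
        rep = make_repertoire(counts)
        bins = bin_expansion(rep)
        by_tag = {tag: bins[make_clone(tag)] for tag in counts}
        assert by_tag["a"] == "unique"
        assert by_tag["b"] == "small"
        assert by_tag["c"] == "medium"
        assert by_tag["d"] == "large"
        assert by_tag["e"] == "hyperexpanded"

    def test_hyperexpanded_above_five_percent(self):
        rep = make_repertoire({"big": 60, "rest": 940})
        assert bin_expansion(rep)[make_clone("big")] == "hyperexpanded"

    def test_singleton_precedes_frequency(self):
        rep = make_repertoire({"solo": 1, "other": 4})
        assert bin_expansion(rep)[make_clone("solo")] == "unique"

    def test_boundaries_half_open(self):
        # counts sitting exactly on each boundary of a pool of 1000 fall into
        # the upper bin (half-open [lo, hi) everywhere, so f = 0.05 is
        # hyperexpanded)
        rep = make_repertoire({"s": 10, "m": 20, "l": 50, "pad": 920})
        bins = {tag: bin_expansion(rep)[make_clone(tag)] for tag in ("s", "m", "l")}
        assert bins == {"s": "medium", "m": "large", "l": "hyperexpanded"}

    def test_empty_repertoire_errors(self):
        with pytest.raises(ValidationError):
            bin_expansion(Repertoire(sample_id="empty"))

    def test_partition_and_monotone_on_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tags = {f"t{i}": int(c) for i, c in enumerate(rng.integers(1, 80, size=20))}
            rep = make_repertoire(tags)
            bins = bin_expansion(rep)
            assert len(bins) == rep.n_clones  # every clone exactly one bin
            order = ["rare", "small", "medium", "large", "hyperexpanded"]
            multi = sorted(
                ((n, bins[c]) for c, n in rep.clone_counts.items() if n > 1),
                key=lambda t: t[0],
            )
            ranks = [order.index(b) for _, b in multi]
            assert ranks == sorted(ranks)  # bin non-decreasing in frequency

    def test_invalid_boundaries(self):
        with pytest.raises(ValidationError):
            ExpansionBinning(rare_max=0.01, small_max=0.01)


class TestExpandedComposition:
    def test_single_label(self):
        x = make_clone("x")
        cells = cells_frame([(f"b{i}", "s1", "p1", "tumor", 1, "cytotoxic CD8", "CD8")
                             for i in range(3)])
        mapping = {f"b{i}": x for i in range(3)}
        rep = build_repertoire(mapping, cells, "s1")
        assert expanded_composition(rep, cells, mapping) == {"cytotoxic CD8": 1.0}

    def test_no_expanded_clones(self):
        cells = cells_frame([("b0", "s1", "p1", "tumor", 1, "T", "CD8")])
        mapping = {"b0": make_clone("solo")}
        rep = build_repertoire(mapping, cells, "s1")
        assert expanded_composition(rep, cells, mapping) == {}

    def test_split_fractions(self):
        x = make_clone("x")
        rows, mapping = [], {}
        for i in range(7):
            rows.append((f"b{i}", "s1", "p1", "tumor", 1, "typeA", "CD8"))
            mapping[f"b{i}"] = x
        for i in range(7, 10):
            rows.append((f"b{i}", "s1", "p1", "tumor", 1, "typeB", "CD8"))
            mapping[f"b{i}"] = x
        cells = cells_frame(rows)
        rep = build_repertoire(mapping, cells, "s1")
        comp = expanded_composition(rep, cells, mapping)
        assert comp == {"typeA": 0.7, "typeB": 0.3}
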