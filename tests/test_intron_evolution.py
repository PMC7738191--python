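import itertools

import pandas as pd
import pytest

from genarch.annotation_io import AnnotationError
from genarch.intron_evolution import (
    ABSENT,
    AMBIGUOUS,
    PRESENT,
    AlignedOrthogroup,
    AlignedSequence,
    IntronSite,
    IntronSiteTable,
    ProteinIntronAnnotation,
    annotate_protein_introns,
    classify_loss_precision,
    dollo_events,
    filter_unambiguous,
    load_species_tree,
    presence_histogram,
    project_sites,
    read_cluster_fasta,
    select_clusters,
    write_cluster_fasta,
)

from helpers import make_transcript


def seq(species, aligned, sites=(), seqid=None):
    degapped = sum(1 for ch in aligned if ch not in "-.")
    annotation = ProteinIntronAnnotation(
        seqid or f"{species}_p1", species, degapped, tuple(sites)
    )
    return AlignedSequence(species, aligned, annotation)


def site_tuple(c):
    return (c, c % 3, c // 3)


class TestAnnotateProteinIntrons:
    def test_phase0_after_one_codon(self):
        t = make_transcript("g", [(1, 3), (101, 397)])  # 3 + 297 nt
        ann = annotate_protein_introns(t)
        assert ann.sites == ((3, 0, 1),)

    def test_phase1(self):
        t = make_transcript("g", [(1, 4), (101, 396)])  # 4 + 296 nt
        ann = annotate_protein_introns(t)
        assert ann.sites == ((4, 1, 1),)

    def test_splice_and_count_oracle(self):
        # 300-nt CDS with introns after 60 and 150 coding nt
        t = make_transcript("g", [(1, 60), (101, 190), (301, 450)])
        ann = annotate_protein_introns(t)
        assert ann.sites == ((60, 0, 20), (150, 0, 50))
        assert ann.protein_length == 100

    def test_non_multiple_of_three_rejected(self):
        t = make_transcript("g", [(1, 50), (101, 151)])
        with pytest.raises(AnnotationError, match="multiple of 3"):
            annotate_protein_introns(t)
        assert annotate_protein_introns(t, allow_partial_codon=True)

    def test_minus_strand_matches_explicit_splice(self):
        t = make_transcript("g", [(101, 160), (261, 460), (561, 600)], strand="-")
        # transcription order lengths: 40, 200, 60 -> junctions at 40, 240
        ann = annotate_protein_introns(t)
        assert [(c, p) for c, p, _ in ann.sites] == [(40, 1), (240, 0)]


class TestProjectSites:
    def test_identical_ungapped_sequences_merge(self):
        cluster = AlignedOrthogroup(
            "c1",
            {
                "sp1": seq("sp1", "MKLVAATTW", [site_tuple(15)]),
                "sp2": seq("sp2", "MKLVAATTW", [site_tuple(15)]),
            },
        )
        table = project_sites(cluster)
        assert len(table.sites) == 1
        site = table.sites[0]
        assert site.column == 5 and site.phase == 0
        assert site.states == {"sp1": PRESENT, "sp2": PRESENT}

    def test_insertion_shifts_column(self):
        # sp2 carries a 2-residue insertion before residue 5, so the two
        # introns annotated at s=5 land 2 columns apart: manual bookkeeping
        # puts sp1's residue 5 at column 7 and sp2's residue 5 at column 5
        cluster = AlignedOrthogroup(
            "c1",
            {
                "sp1": seq("sp1", "MKLVA--TTWQ", [site_tuple(15)]),
                "sp2": seq("sp2", "MKLVAGGTTWQ", [site_tuple(15)]),
            },
        )
        table = project_sites(cluster)
        columns = sorted((s.column, s.phase) for s in table.sites)
        assert columns == [(5, 0), (7, 0)]
        states = {s.column: s.states for s in table.sites}
        assert states[7] == {"sp1": PRESENT, "sp2": ABSENT}
        assert states[5] == {"sp1": ABSENT, "sp2": PRESENT}

    def test_same_column_different_phase_distinct(self):
        cluster = AlignedOrthogroup(
            "c1",
            {
                "sp1": seq("sp1", "MKLVAATTW", [site_tuple(15)]),
                "sp2": seq("sp2", "MKLVAATTW", [site_tuple(16)]),
            },
        )
        table = project_sites(cluster)
        assert sorted((s.column, s.phase) for s in table.sites) == [(5, 0), (5, 1)]

    def test_missing_species_ambiguous(self):
        cluster = AlignedOrthogroup(
            "c1", {"sp1": seq("sp1", "MKLVAATTW", [site_tuple(15)])}
        )
        table = project_sites(cluster, roster=["sp1", "sp2"])
        assert table.sites[0].states == {"sp1": PRESENT, "sp2": AMBIGUOUS}

    def test_projection_round_trip(self):
        aligned = "M--KLV-AATTW"
        s = seq("sp1", aligned, [site_tuple(9), site_tuple(22)])
        columns = s.residue_columns()
        for c, p, residue_index in s.annotation.sites:
            column = columns[residue_index]
            # invert: count non-gaps left of the column
            recovered = sum(1 for ch in aligned[:column] if ch not in "-.")
            assert recovered == residue_index


def _flanked(core, introns=()):
    """Pad a 1-residue core with 6 residues each side."""
    return seq(core, "ABCDEF" + "K" + "ABCDEF", introns)


class TestFilterUnambiguous:
    def make_cluster(self, n_species=13, gap_species=()):
        sequences = {}
        for i in range(n_species):
            name = f"sp{i:02d}"
            if name in gap_species:
                aligned = "----EF" + "K" + "ABCDEF"  # only 2 residues left of col 6
            else:
                aligned = "ABCDEF" + "K" + "ABCDEF"
            sites = [site_tuple(3 * sum(1 for ch in aligned[:6] if ch != "-"))]
            sequences[name] = seq(name, aligned, sites)
        return AlignedOrthogroup("c1", sequences)

    def test_focal_with_thin_flank_drops_site(self):
        cluster = self.make_cluster(gap_species=("sp00",))
        table = project_sites(cluster)
        out = filter_unambiguous(table, cluster, focal="sp00")
        assert out.sites == []

    def test_enough_unambiguous_others_retained(self):
        cluster = self.make_cluster(n_species=13)
        table = project_sites(cluster)
        out = filter_unambiguous(table, cluster, focal="sp00", min_other_species=11)
        assert len(out.sites) == 1

    def test_too_few_others_dropped(self):
        cluster = self.make_cluster(n_species=12)
        table = project_sites(cluster)
        assert (
            filter_unambiguous(table, cluster, "sp00", min_other_species=12).sites
            == []
        )

    def test_permissive_settings_keep_everything(self):
        cluster = self.make_cluster(n_species=6, gap_species=("sp01", "sp02"))
        table = project_sites(cluster)
        out = filter_unambiguous(
            table, cluster, "sp00", min_flank=0, min_other_species=1
        )
        assert len(out.sites) == len(table.sites)

    def test_monotone_in_parameters(self):
        cluster = self.make_cluster(n_species=13, gap_species=("sp05",))
        table = project_sites(cluster)
        kept = {}
        for flank, others in itertools.product([0, 3, 5, 7], [1, 5, 11, 12]):
            out = filter_unambiguous(table, cluster, "sp00", flank, others)
            kept[(flank, others)] = {(s.column, s.phase) for s in out.sites}
        for (f1, o1), sites1 in kept.items():
            for (f2, o2), sites2 in kept.items():
                if f2 >= f1 and o2 >= o1:
                    assert sites2 <= sites1


class TestSelectClusters:
    def matrix(self, rows):
        return pd.DataFrame(rows).T  # rows: dict cluster -> dict species -> count

    def test_passing_cluster_kept(self):
        roster = ["focal"] + [f"o{i}" for i in range(17)]
        counts = {sp: 1 for sp in roster[:15]} | {sp: 0 for sp in roster[15:]}
        df = pd.DataFrame([counts], index=["c1"])
        assert select_clusters(df, "focal") == ["c1"]

    def test_species_over_copy_limit_dropped(self):
        roster = ["focal"] + [f"o{i}" for i in range(17)]
        counts = {sp: 1 for sp in roster}
        counts["o3"] = 4
        df = pd.DataFrame([counts], index=["c1"])
        assert select_clusters(df, "focal") == []

    def test_too_few_other_species_dropped(self):
        roster = ["focal"] + [f"o{i}" for i in range(17)]
        counts = {sp: 0 for sp in roster}
        counts["focal"] = 1
        for i in range(13):
            counts[f"o{i}"] = 2
        df = pd.DataFrame([counts], index=["c1"])
        assert select_clusters(df, "focal") == []
        assert select_clusters(df, "focal", min_other_species=13) == ["c1"]

    def test_missing_focal_is_error(self):
        df = pd.DataFrame([{"a": 1}], index=["c1"])
        with pytest.raises(KeyError):
            select_clusters(df, "focal")


def quartet_tree():
    return load_species_tree("((A,B),(C,D));")


def make_table(states_by_site, roster=("A", "B", "C", "D")):
    sites = [
        IntronSite(column=i, phase=0, states=dict(zip(roster, states)))
        for i, states in enumerate(states_by_site)
    ]
    return IntronSiteTable("t", tuple(roster), sites)


class TestDolloEvents:
    def test_all_present_single_root_gain(self):
        table = make_table([[PRESENT] * 4])
        tallies = dollo_events(table, quartet_tree())
        assert tallies.total_gains == 1
        assert tallies.gains_for("A", "B", "C", "D") == 1
        assert tallies.total_losses == 0

    def test_alternating_pattern_two_losses(self):
        table = make_table([[PRESENT, ABSENT, PRESENT, ABSENT]])
        tallies = dollo_events(table, quartet_tree())
        assert tallies.gains_for("A", "B", "C", "D") == 1
        assert tallies.total_losses == 2
        assert tallies.losses_for("B") == 1
        assert tallies.losses_for("D") == 1

    def test_clade_pattern_gain_at_mrca(self):
        table = make_table([[PRESENT, PRESENT, ABSENT, ABSENT]])
        tallies = dollo_events(table, quartet_tree())
        assert tallies.gains_for("A", "B") == 1
        assert tallies.total_losses == 0

    def test_ambiguous_leaves_avoid_losses(self):
        table = make_table([[PRESENT, AMBIGUOUS, PRESENT, AMBIGUOUS]])
        tallies = dollo_events(table, quartet_tree())
        assert tallies.gains_for("A", "B", "C", "D") == 1
        assert tallies.total_losses == 0

    def test_whole_clade_absence_is_one_loss(self):
        table = make_table([[PRESENT, PRESENT, ABSENT, ABSENT]])
        tree = load_species_tree("(((A,B),(C,D)),E);")
        table = IntronSiteTable(
            "t",
            ("A", "B", "C", "D", "E"),
            [
                IntronSite(
                    0,
                    0,
                    {
                        "A": PRESENT,
                        "B": PRESENT,
                        "C": ABSENT,
                        "D": ABSENT,
                        "E": PRESENT,
                    },
                )
            ],
        )
        tallies = dollo_events(table, tree)
        assert tallies.total_losses == 1
        assert tallies.losses_for("C", "D") == 1

    def test_no_present_species_is_error(self):
        table = make_table([[ABSENT] * 4])
        with pytest.raises(ValueError, match="no present species"):
            dollo_events(table, quartet_tree())

    def test_unrooted_tree_rejected(self):
        with pytest.raises(ValueError, match="rooted"):
            load_species_tree("(A,B,C);")


class TestPresenceHistogram:
    def test_counts_by_presence(self):
        roster = tuple(f"s{i}" for i in range(6))
        sites = []
        for n_present in (2, 2, 5):
            states = {
                sp: (PRESENT if i < n_present else ABSENT)
                for i, sp in enumerate(roster)
            }
            sites.append(IntronSite(len(sites), 0, states))
        table = IntronSiteTable("t", roster, sites)
        assert presence_histogram(table) == {2: 2, 5: 1}

    def test_invariant_under_species_reordering(self):
        roster = ("a", "b", "c")
        sites = [IntronSite(0, 0, {"a": PRESENT, "b": ABSENT, "c": PRESENT})]
        table = IntronSiteTable("t", roster, sites)
        reordered = IntronSiteTable(
            "t",
            ("c", "b", "a"),
            [IntronSite(0, 0, {"c": PRESENT, "b": ABSENT, "a": PRESENT})],
        )
        assert presence_histogram(table) == presence_histogram(reordered)


class TestClassifyLossPrecision:
    def flush_cluster(self):
        sequences = {
            "focal": seq("focal", "ABCDEFKABCDEF"),
            "sp1": seq("sp1", "ABCDEFKABCDEF", [site_tuple(18)]),
            "sp2": seq("sp2", "ABCDEFKABCDEF", [site_tuple(18)]),
        }
        return AlignedOrthogroup("c1", sequences)

    def test_flush_alignment_is_precise(self):
        cluster = self.flush_cluster()
        table = project_sites(cluster)
        call = classify_loss_precision(cluster, table.sites[0], "focal")
        assert call.verdict == "precise"
        assert call.indel_residues == 0

    def test_planted_insertion_is_imprecise(self):
        sequences = {
            "focal": seq("focal", "ABCDEFSNKABCDEF"),
            "sp1": seq("sp1", "ABCDEF--KABCDEF", [site_tuple(18)]),
            "sp2": seq("sp2", "ABCDEF--KABCDEF", [site_tuple(18)]),
        }
        cluster = AlignedOrthogroup("c1", sequences)
        table = project_sites(cluster)
        call = classify_loss_precision(cluster, table.sites[0], "focal")
        assert call.verdict == "imprecise"
        assert call.indel_residues == 2

    def test_focal_present_is_usage_error(self):
        cluster = self.flush_cluster()
        site = IntronSite(6, 0, {"focal": PRESENT, "sp1": PRESENT, "sp2": PRESENT})
        with pytest.raises(ValueError, match="carries the intron"):
            classify_loss_precision(cluster, site, "focal")


class TestClusterFastaRoundTrip:
    def test_round_trip(self, tmp_path):
        sequences = {
            "sp1": seq("sp1", "MK-LVAATTW", [site_tuple(9)]),
            "sp2": seq("sp2", "MKALVAATTW", [site_tuple(12), site_tuple(20)]),
            "sp3": seq("sp3", "MKALVAATT-"),
        }
        cluster = AlignedOrthogroup("c9", sequences)
        path = tmp_path / "c9.fasta"
        write_cluster_fasta(cluster, path)
        reread = read_cluster_fasta(path, "c9")
        assert set(reread.sequences) == set(sequences)
        for sp in sequences:
            assert reread.sequences[sp].aligned == sequences[sp].aligned
            assert (
                reread.sequences[sp].annotation.sites
                == sequences[sp].annotation.sites
            )
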