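import numpy as np
import pytest

from cyanomine import precursor_miner as pm
from cyanomine import references
from cyanomine.seqio import GeneFeature, GenomeRecord, reverse_complement
from cyanomine.synthetic_data import back_translate, mutate_protein


class TestLeaderMotifs:
    def test_double_glycine_consensus_match(self):
        prot = "MRELSAAEISQVAGG" + "WTNCSTGCAST"
        m = pm.match_leader_motif(prot, pm.GG_LEADER)
        assert m is not None and (m.motif, m.offset, m.cleavage_index) == ("GG", 0, 15)

    def test_lysine_and_gly_ala_variants(self):
        prot = "MKELQQQELAAIAGA" + "WTNCSTGCAST"
        m = pm.match_leader_motif(prot, pm.GG_LEADER)
        assert m is not None and m.cleavage_index == 15

    def test_hetp_leader_match(self):
        prot = "KIADLAYLEAAAAAAAAAAGG" + "WTNCSTGCAST"
        m = pm.match_leader_motif(prot, pm.HETP_LEADER)
        assert m is not None and (m.motif, m.cleavage_index) == ("HETP", 21)

    def test_rightmost_match_within_leader_region_wins(self):
        block = "MRELSAAEISQVAGG"
        prot = block + block + "WTNCSTGCAST"
        m = pm.match_leader_motif(prot, pm.GG_LEADER)
        assert m.offset == 15 and m.cleavage_index == 30

    def test_match_beyond_n_terminal_region_ignored(self):
        prot = "A" * 80 + "MRELSAAEISQVAGG" + "WTN"
        assert pm.match_leader_motif(prot, pm.GG_LEADER) is None

    def test_no_match_is_none(self):
        assert pm.match_leader_motif("MAAAAAAAAAAAAAAAAAAAA", pm.GG_LEADER) is None

    def test_permissive_mode_accepts_bare_dipeptide(self):
        prot = "MAAAAGG" + "WTNCST"
        assert pm.match_leader_motif(prot, pm.GG_LEADER) is None
        m = pm.match_permissive_gg(prot)
        assert m is not None and m.cleavage_index == 7


class TestFindSmallOrfs:
    def _genome_with_planted_orf(self, strand):
        rng = np.random.default_rng(37)
        bases = "ACGT"
        bg = "".join(bases[i] for i in rng.integers(0, 4, 6000))
        protein = "M" + "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 59)
        )
        dna = "TAA" + back_translate(protein, rng) + "TAA"
        if strand == -1:
            dna = reverse_complement(dna)
        pos = 3000
        seq = bg[:pos] + dna + bg[pos + len(dna):]
        start = pos + 3 if strand == +1 else pos
        end = pos + len(dna) if strand == +1 else pos + len(dna) - 3
        big = GeneFeature("big", 200, 200 + 603, +1, "CDS", "M" * 200)
        return GenomeRecord("t", seq, [big]), protein, (start, end, strand)

    @pytest.mark.parametrize("strand", [+1, -1])
    def test_planted_unannotated_orf_recovered(self, strand):
        genome, protein, (start, end, st) = self._genome_with_planted_orf(strand)
        orfs = pm.find_small_orfs(genome, (0, len(genome.sequence)))
        match = [o for o in orfs if (o.start, o.end, o.strand) == (start, end, st)]
        assert len(match) == 1
        assert match[0].protein == protein and not match[0].annotated

    def test_oversized_cds_excluded_by_length_bound(self):
        genome, *_ = self._genome_with_planted_orf(+1)
        orfs = pm.find_small_orfs(genome, (0, 1000))
        assert all(o.orf_id != "big" for o in orfs)

    def test_annotated_small_cds_included(self):
        genome, protein, _ = self._genome_with_planted_orf(+1)
        genome.features.append(GeneFeature("small", 900, 900 + 153, +1, "CDS", "M" * 50))
        genome.features.sort(key=lambda f: f.start)
        orfs = pm.find_small_orfs(genome, (0, 2000))
        assert any(o.orf_id == "small" and o.annotated for o in orfs)

    def test_window_clipped_at_contig_ends(self):
        genome, *_ = self._genome_with_planted_orf(+1)
        orfs = pm.find_small_orfs(genome, (-5000, len(genome.sequence) + 5000))
        assert all(0 <= o.start < o.end <= len(genome.sequence) for o in orfs)


class TestAssignFamily:
    def test_exact_seed_copy_assigned_to_its_family(self):
        seeds = references.precursor_seed_families()
        assert pm.assign_family(seeds["NHLP"].members[0][1], seeds) == "NHLP"

    def test_mutated_seed_keeps_family(self):
        rng = np.random.default_rng(41)
        seeds = references.precursor_seed_families()
        prot = mutate_protein(seeds["N11P"].members[1][1], 0.10, rng)
        assert pm.assign_family(prot, seeds) == "N11P"

    def test_shuffled_seed_is_other_in_95pct_of_trials(self):
        rng = np.random.default_rng(43)
        seeds = references.precursor_seed_families()
        base = list(seeds["NHLP"].members[0][1])
        other = sum(
            pm.assign_family("".join(rng.permutation(base)), seeds) == "OTHER"
            for _ in range(100)
        )
        assert other >= 95


class TestPeptideFeatures:
    def test_glycine_is_near_neutral_at_ph7(self):
        charge, pi, mw = pm.peptide_features("G")
        assert abs(charge) < 0.05
        assert mw == pytest.approx(75.07, abs=0.1)

    def test_poly_aspartate_is_acidic(self):
        charge, pi, _ = pm.peptide_features("D" * 10)
        assert charge < -5 and pi < 7

    def test_poly_lysine_is_basic(self):
        charge, pi, _ = pm.peptide_features("K" * 10)
        assert charge > 5 and pi > 7

    def test_pi_zeroes_net_charge(self):
        prot = "MKTAYIAKQRDE"
        pi = pm.isoelectric_point(prot)
        assert abs(pm.net_charge(prot, pi)) < 1e-3

    def test_unknown_residue_contributes_mass_but_no_charge(self):
        assert pm.net_charge("GXG") == pytest.approx(pm.net_charge("GG"), abs=1e-9)
        assert pm.molecular_weight("X") == pytest.approx(110.0 + 18.0153)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pm.peptide_features("")


class TestMinedPrecursors:
    def test_all_sixteen_planted_precursors_recovered(self, dense_precursor_run):
        truth = dense_precursor_run["truth"].of_kind("precursor")
        found = {(p.start, p.end, p.strand): p for p in dense_precursor_run["precursors"]}
        assert len(truth) == 16
        for r in truth:
            p = found.get((r.start, r.end, r.strand))
            assert p is not None, r.id
            assert (p.motif, p.cleavage_index, p.family, p.novel) == (
                r.motif, r.cleavage_index, r.family, r.novel
            ), r.id

    def test_precision_against_decoys(self, dense_precursor_run):
        planted = {
            (r.start, r.end, r.strand)
            for r in dense_precursor_run["truth"].of_kind("precursor")
        }
        found = dense_precursor_run["precursors"]
        tp = sum((p.start, p.end, p.strand) in planted for p in found)
        assert tp / len(found) >= 0.9

    def test_leader_core_concatenation_identity(self, dense_precursor_run):
        for p in dense_precursor_run["precursors"]:
            assert p.leader + p.core == p.protein
            assert p.motif != "GG" or p.leader[-2] == "G"

    def test_family_charge_signs_match_generator_configuration(self, dense_precursor_run):
        """NHLP/N11P precursors are acidic, HetP/DUF37 basic — the planted
        analogue of the opposite charge states of the two family pairs."""
        for p in dense_precursor_run["precursors"]:
            if p.family in ("NHLP", "N11P"):
                assert p.net_charge < 0, p.orf_id
            elif p.family in ("HETP", "DUF37"):
                assert p.net_charge > 0, p.orf_id

    def test_precursor_lengths_within_scan_bounds(self, dense_precursor_run):
        for p in dense_precursor_run["precursors"]:
            assert 25 <= p.length <= 170

    def test_table_export_contains_all_candidates(self, dense_precursor_run):
        table = pm.precursor_table(dense_precursor_run["precursors"])
        assert table.count("\n") == len(dense_precursor_run["precursors"]) + 1
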