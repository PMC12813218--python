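"""Tryptic digestion, peptide location and region assignment."""

import numpy as np
import pytest

from plf.digest_mapping import (DigestParams, LocatedPeptide, PeptideNotFound,
                                assign_regions, build_region_matrix,
                                locate_peptide, region_bounds, region_count,
                                tryptic_digest)
from plf.io_formats import PeptideObservation, ProteinRecord

from oracles import oracle_digest

NO_FILTER = DigestParams(apply_length_filter=False)


class TestTrypticDigest:
    def test_no_cleavage_site_yields_whole_sequence(self):
        peps = tryptic_digest("AAAA", NO_FILTER)
        assert {(p.start, p.end, p.peptide_sequence) for p in peps} == {(1, 4, "AAAA")}

    def test_proline_suppresses_cleavage(self):
        # K before P is not cut; R at the C-terminus needs no cut
        peps = tryptic_digest("AKPR", DigestParams(max_missed_cleavages=0,
                                                   apply_length_filter=False))
        assert {p.peptide_sequence for p in peps} == {"AKPR"}

    def test_basic_cleavage_with_missed(self):
        peps = tryptic_digest("AAKGGRCC", NO_FILTER)
        spans = {(p.start, p.end) for p in peps}
        # 0 missed: AAK, GGR, CC; 1 missed: AAKGGR, GGRCC
        assert spans == {(1, 3), (4, 6), (7, 8), (1, 6), (4, 8)}

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("")

    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, max_missed):
        """Digest equals substring-legality enumeration on random sequences."""
        rng = np.random.default_rng(1234 + max_missed)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(40):
            seq = "".join(rng.choice(alphabet, size=200,
                                     p=_kr_profile(alphabet)))
            params = DigestParams(max_missed_cleavages=max_missed,
                                  apply_length_filter=False)
            got = {(p.start, p.end) for p in tryptic_digest(seq, params)}
            assert got == oracle_digest(seq, max_missed)

    def test_length_filter_matches_oracle_window(self):
        rng = np.random.default_rng(7)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seq = "".join(rng.choice(alphabet, size=300, p=_kr_profile(alphabet)))
        got = {(p.start, p.end) for p in tryptic_digest(seq, DigestParams())}
        assert got == oracle_digest(seq, 1, (6, 25))


def _kr_profile(alphabet):
    p = np.full(len(alphabet), (1 - 0.11) / 18)
    p[np.isin(alphabet, ["K", "R"])] = 0.11 / 2
    return p


class TestLocatePeptide:
    PROT = ProteinRecord("P1", "P1", "GPAGKRGPAGK")

    def test_first_occurrence(self):
        hits = locate_peptide(self.PROT, "GPAGK", "first")
        assert [(h.start, h.end) for h in hits] == [(1, 5)]

    def test_all_occurrences(self):
        hits = locate_peptide(self.PROT, "GPAGK", "all")
        assert [(h.start, h.end) for h in hits] == [(1, 5), (7, 11)]

    def test_error_policy_on_ambiguity(self):
        with pytest.raises(ValueError):
            locate_peptide(self.PROT, "GPAGK", "error")

    def test_not_found(self):
        with pytest.raises(PeptideNotFound, match="WWW"):
            locate_peptide(self.PROT, "WWW")


class TestAssignRegions:
    def test_single_region(self):
        a = assign_regions(LocatedPeptide("P", 1, 10, "A" * 10), 50, "full")
        assert [(x.region_index, x.overlap_residues, x.weight) for x in a] \
            == [(0, 10, 1.0)]

    def test_proportional_split_across_boundary(self):
        a = assign_regions(LocatedPeptide("P", 45, 55, "A" * 11), 50,
                           "proportional")
        assert [(x.region_index, x.overlap_residues) for x in a] == [(0, 6), (1, 5)]
        assert a[0].weight == pytest.approx(6 / 11)
        assert a[1].weight == pytest.approx(5 / 11)
        assert sum(x.weight for x in a) == pytest.approx(1.0)

    def test_full_policy_double_counts_boundary(self):
        a = assign_regions(LocatedPeptide("P", 45, 55, "A" * 11), 50, "full")
        assert [(x.region_index, x.weight) for x in a] == [(0, 1.0), (1, 1.0)]

    def test_start_policy(self):
        a = assign_regions(LocatedPeptide("P", 45, 55, "A" * 11), 50, "start")
        assert [(x.region_index, x.weight) for x in a] == [(0, 1.0)]

    def test_overlap_residues_cover_peptide(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            start = int(rng.integers(1, 500))
            length = int(rng.integers(1, 60))
            pep = LocatedPeptide("P", start, start + length - 1, "A" * length)
            for policy in ("full", "proportional"):
                a = assign_regions(pep, 50, policy)
                assert sum(x.overlap_residues for x in a) == length


class TestRegionGeometry:
    def test_region_widths_sum_to_protein_length(self):
        for length in (1, 49, 50, 51, 120, 1372):
            n = region_count(length)
            widths = [region_bounds(k, 50, length)[1]
                      - region_bounds(k, 50, length)[0] + 1
                      for k in range(n)]
            assert sum(widths) == length
            assert widths[-1] <= 50
            assert all(w == 50 for w in widths[:-1])


class TestBuildRegionMatrix:
    def test_single_observation(self, toy_protein, design_3v3):
        pep = toy_protein.sequence[0:9]  # ends at the K at position 9
        o = PeptideObservation("juvenile_male_1", toy_protein.accession, pep, 7)
        res = build_region_matrix([o], {toy_protein.accession: toy_protein},
                                  design_3v3)
        m = res.matrices[toy_protein.accession]
        s = m.sample_index("juvenile_male_1")
        assert m.values[s].tolist() == [7, 0, 0]
        assert m.totals[s] == 7

    def test_identical_observations_identical_rows(self, toy_protein, design_3v3):
        pep = toy_protein.sequence[0:9]
        obs = [PeptideObservation(s.sample_id, toy_protein.accession, pep, 4)
               for s in design_3v3.samples]
        res = build_region_matrix(obs, {toy_protein.accession: toy_protein},
                                  design_3v3)
        m = res.matrices[toy_protein.accession]
        assert (m.values == m.values[0]).all()

    def test_unknown_accession_routed_to_rejects(self, toy_protein, design_3v3):
        o = PeptideObservation("juvenile_male_1", "NOPE", "AAAAAA", 3)
        res = build_region_matrix([o], {toy_protein.accession: toy_protein},
                                  design_3v3)
        assert res.matrices == {}
        assert list(res.rejects["reason"]) == ["accession not in FASTA"]

    def test_unlocatable_peptide_routed_to_rejects(self, toy_protein, design_3v3):
        o = PeptideObservation("juvenile_male_1", toy_protein.accession,
                               "WWWWWW", 3)
        res = build_region_matrix([o], {toy_protein.accession: toy_protein},
                                  design_3v3)
        assert res.n_unlocatable == 1

    def test_proportional_policy_conserves_totals(self, toy_protein, design_3v3):
        """Row sums equal per-sample totals exactly under proportional split."""
        rng = np.random.default_rng(5)
        peps = tryptic_digest(toy_protein.sequence, NO_FILTER)
        obs = []
        for s in design_3v3.samples:
            for p in peps:
                obs.append(PeptideObservation(
                    s.sample_id, toy_protein.accession, p.peptide_sequence,
                    int(rng.integers(0, 20))))
        res = build_region_matrix(obs, {toy_protein.accession: toy_protein},
                                  design_3v3, overlap_policy="proportional")
        m = res.matrices[toy_protein.accession]
        assert np.allclose(m.values.sum(axis=1), m.totals, atol=1e-9)

    def test_full_policy_region_sums_at_least_totals(self, toy_protein,
                                                     design_3v3):
        rng = np.random.default_rng(6)
        peps = tryptic_digest(toy_protein.sequence, NO_FILTER)
        obs = [PeptideObservation("juvenile_male_1", toy_protein.accession,
                                  p.peptide_sequence, int(rng.integers(1, 9)))
               for p in peps]
        res = build_region_matrix(obs, {toy_protein.accession: toy_protein},
                                  design_3v3, overlap_policy="full")
        m = res.matrices[toy_protein.accession]
        s = m.sample_index("juvenile_male_1")
        assert m.values[s].sum() >= m.totals[s]


from hypothesis import given, settings, strategies as st


@st.composite
def protein_sequences(draw):
    return "".join(draw(st.lists(
        st.sampled_from("ACDEFGHIKLMNPQRSTVWYKRKR"),  # K/R enriched
        min_size=1, max_size=120)))


class TestDigestProperties:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(seq=protein_sequences(), mc=st.integers(0, 2))
    def test_digest_always_matches_oracle(self, seq, mc):
        params = DigestParams(max_missed_cleavages=mc,
                              apply_length_filter=False)
        got = {(p.start, p.end) for p in tryptic_digest(seq, params)}
        assert got == oracle_digest(seq, mc)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seq=protein_sequences(), mc=st.integers(0, 2))
    def test_peptides_tile_the_sequence_at_zero_missed(self, seq, mc):
        """0-missed peptides exactly tile the sequence; higher missed-
        cleavage sets always contain the 0-missed set."""
        params0 = DigestParams(max_missed_cleavages=0,
                               apply_length_filter=False)
        frags = sorted((p.start, p.end) for p in tryptic_digest(seq, params0))
        assert frags[0][0] == 1 and frags[-1][1] == len(seq)
        assert all(a[1] + 1 == b[0] for a, b in zip(frags, frags[1:]))
        params = DigestParams(max_missed_cleavages=mc,
                              apply_length_filter=False)
        got = {(p.start, p.end) for p in tryptic_digest(seq, params)}
        assert set(frags) <= got

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(start=st.integers(1, 400), length=st.integers(1, 80),
           region_size=st.integers(5, 60))
    def test_assignment_weights(self, start, length, region_size):
        pep = LocatedPeptide("P", start, start + length - 1, "A" * length)
        prop = assign_regions(pep, region_size, "proportional")
        assert sum(a.weight for a in prop) == pytest.approx(1.0)
        full = assign_regions(pep, region_size, "full")
        assert all(a.weight == 1.0 for a in full)
        assert [a.region_index for a in full] \
            == [a.region_index for a in prop]
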