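"""OFR profiles, threshold test, binomial matrix and percent resolution."""

import numpy as np
import pytest

from ofrbarcode import (
    BarcodeDataset,
    OFRProfile,
    SequenceRecord,
    SimSpec,
    generate_dataset,
    kmer_frequencies,
    percent_resolution,
    resolution_matrix,
    resolve_pair,
    species_ofr,
    threshold,
)
from ofrbarcode.errors import ConfigError, InvalidLengthError, UndefinedScoreError

from conftest import make_dataset


class TestThreshold:
    def test_dinucleotide_formula(self):
        assert threshold(651, 2).t == pytest.approx(1 / 650)

    def test_trinucleotide_formula(self):
        assert threshold(651, 3).t == pytest.approx(1 / 649)

    def test_monotone_decreasing_in_length(self):
        grid = np.linspace(100, 1700, 33)
        for k in (2, 3):
            ts = [threshold(a, k).t for a in grid]
            assert all(b < a for a, b in zip(ts, ts[1:]))

    def test_too_short_average(self):
        with pytest.raises(InvalidLengthError):
            threshold(2, 3)


class TestSpeciesOFR:
    def test_two_accession_minmax(self):
        ds = make_dataset({"A": ["AAAA", "AAAT"], "B": ["CCCC", "CCCC"]})
        prof = species_ofr(ds, "A", 2)
        r = prof.ranges
        assert (r["AA"].lo, r["AA"].hi) == (pytest.approx(2 / 3), 1.0)
        assert (r["AT"].lo, r["AT"].hi) == (0.0, pytest.approx(1 / 3))

    def test_single_accession_degenerate(self):
        ds = make_dataset({"A": ["ACGTACGT"], "B": ["ACGTACGT"]})
        prof = species_ofr(ds, "A", 2)
        assert np.array_equal(prof.lo, prof.hi)

    def test_unknown_species(self, two_species_ds):
        with pytest.raises(ConfigError):
            species_ofr(two_species_ds, "nope", 2)

    def test_matches_per_accession_oracle(self):
        ds, _ = generate_dataset(
            SimSpec(n_species=2, accessions_per_species=10, seed=8)
        )
        sp = ds.species_ids[0]
        prof = species_ofr(ds, sp, 3)
        vecs = np.stack(
            [
                kmer_frequencies(r.residues, 3).vector
                for r in ds.species_index[sp]
            ]
        )
        assert np.allclose(prof.lo, vecs.min(axis=0))
        assert np.allclose(prof.hi, vecs.max(axis=0))


def _profile(lo, hi, k=2, n=2, name="X"):
    z = np.zeros(4**k)
    lo_v, hi_v = z.copy(), z.copy()
    lo_v[0], hi_v[0] = lo, hi
    return OFRProfile(species_id=name, k=k, lo=lo_v, hi=hi_v, n_accessions=n)


class TestResolvePair:
    def test_clear_gap(self):
        ts = threshold(101, 2)  # t = 0.01
        pr = resolve_pair(_profile(0.10, 0.12, name="A"), _profile(0.20, 0.25, name="B"), ts)
        assert pr.resolved
        assert pr.max_gap == pytest.approx(0.08)

    def test_identical_profiles_unresolved(self):
        ts = threshold(101, 2)
        pa, pb = _profile(0.1, 0.2, name="A"), _profile(0.1, 0.2, name="B")
        pr = resolve_pair(pa, pb, ts)
        assert pr.status == "unresolved"
        assert pr.max_gap <= 0

    def test_boundary_inclusive_at_t(self):
        ts = threshold(101, 2)
        t = ts.t
        at = resolve_pair(_profile(0.1, 0.1, name="A"), _profile(0.1 + t, 0.1 + t, name="B"), ts)
        below = resolve_pair(
            _profile(0.1, 0.1, name="A"),
            _profile(0.1 + t - 1e-6, 0.1 + t - 1e-6, name="B"),
            ts,
        )
        assert at.resolved  # "at least t" is inclusive
        assert not below.resolved

    def test_symmetric_including_oligo_set(self):
        ts = threshold(101, 2)
        pa, pb = _profile(0.1, 0.12, name="A"), _profile(0.2, 0.22, name="B")
        ab, ba = resolve_pair(pa, pb, ts), resolve_pair(pb, pa, ts)
        assert ab.resolved == ba.resolved
        assert ab.discriminating_oligos == ba.discriminating_oligos
        assert ab.max_gap == ba.max_gap

    def test_mismatched_k(self):
        with pytest.raises(ConfigError):
            resolve_pair(_profile(0, 1, k=2), _profile(0, 1, k=3), threshold(100, 2))

    def test_insufficient_accessions_not_evaluable(self):
        ts = threshold(101, 2)
        pr = resolve_pair(_profile(0.1, 0.1, n=1), _profile(0.9, 0.9), ts)
        assert pr.status == "not_evaluable"
        assert not pr.resolved


class TestResolutionMatrix:
    def test_identical_species_all_zero(self):
        ds = make_dataset({"A": ["ACGT" * 30] * 2, "B": ["ACGT" * 30] * 2})
        rm = resolution_matrix(ds, 2)
        assert rm.cells[0, 1] == 0.0

    def test_engineered_single_resolved_pair(self):
        a_seq = "A" * 80 + "C" * 20
        b_seq = "A" * 20 + "C" * 80
        ds = make_dataset(
            {"A": [a_seq] * 2, "B": [b_seq] * 2, "C": [a_seq, b_seq]}
        )
        rm = resolution_matrix(ds, 2)
        frame = rm.to_frame()
        assert frame.loc["A", "B"] == 1.0
        assert frame.loc["A", "C"] == 0.0
        assert frame.loc["B", "C"] == 0.0
        assert percent_resolution(rm, "pairs") == pytest.approx(100 / 3)
        assert percent_resolution(rm, "species") == 0.0

    def test_symmetry_on_synthetic(self, benchmark_ds):
        rm = resolution_matrix(benchmark_ds, 2)
        c = rm.cells.copy()
        np.fill_diagonal(c, 0.0)
        assert np.array_equal(c, c.T)

    def test_requires_two_species(self):
        ds = make_dataset({"A": ["ACGT" * 10] * 2})
        with pytest.raises(ConfigError):
            resolution_matrix(ds, 2)


class TestPercentResolution:
    def _matrix(self, cells):
        ids = [f"S{i}" for i in range(len(cells))]
        from ofrbarcode.ofr_core import ResolutionMatrix, ThresholdSpec

        return ResolutionMatrix(ids, np.array(cells, dtype=float), {}, ThresholdSpec(2, 100))

    def test_all_ones(self):
        rm = self._matrix([[np.nan, 1, 1], [1, np.nan, 1], [1, 1, np.nan]])
        assert percent_resolution(rm, "species") == 100.0
        assert percent_resolution(rm, "pairs") == 100.0

    def test_all_zero(self):
        rm = self._matrix([[np.nan, 0], [0, np.nan]])
        assert percent_resolution(rm, "species") == 0.0
        assert percent_resolution(rm, "pairs") == 0.0

    def test_single_resolved_pair_of_three(self):
        rm = self._matrix([[np.nan, 1, 0], [1, np.nan, 0], [0, 0, np.nan]])
        assert percent_resolution(rm, "pairs") == pytest.approx(100 / 3)
        assert percent_resolution(rm, "species") == 0.0

    def test_no_evaluable_pairs(self):
        rm = self._matrix([[np.nan, np.nan], [np.nan, np.nan]])
        with pytest.raises(UndefinedScoreError):
            percent_resolution(rm, "pairs")


class TestSamplingAntiMonotonicity:
    def test_ranges_widen_and_pairs_only_unresolve(self):
        """Adding accessions can only widen OFRs; resolution never appears."""
        ds, _ = generate_dataset(
            SimSpec(n_species=4, accessions_per_species=8, intra_div=0.02, seed=21)
        )
        prev_status = None
        prev_lo = prev_hi = None
        for n_acc in range(2, 9):
            sub = BarcodeDataset(
                [
                    r
                    for r in ds.records
                    if int(r.accession_id[1:]) <= n_acc
                ]
            )
            sp = sub.species_ids[0]
            prof = species_ofr(sub, sp, 2)
            if prev_lo is not None:
                assert np.all(prof.lo <= prev_lo + 1e-15)
                assert np.all(prof.hi >= prev_hi - 1e-15)
            prev_lo, prev_hi = prof.lo, prof.hi
            rm = resolution_matrix(sub, 2)
            status = {
                k: v.resolved for k, v in rm.evidence.items()
            }
            if prev_status is not None:
                for pair, resolved in status.items():
                    if resolved:
                        assert prev_status[pair], (
                            "pair became resolved with more accessions"
                        )
            prev_status = status

    def test_identical_accessions_never_resolve(self):
        ds = make_dataset({"A": ["ACGT" * 25] * 3, "B": ["ACGT" * 25] * 3})
        rm = resolution_matrix(ds, 3)
        assert percent_resolution(rm, "pairs") == 0.0

    def test_scale_consistency_doubling_length_halves_t(self):
        a, k = 400, 2
        assert threshold(2 * a - (k - 1) * 1, k).t < threshold(a, k).t
        assert threshold(2 * (a - 1) + 1, 2).t == pytest.approx(threshold(a, 2).t / 2)
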