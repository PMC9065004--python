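"""Matching and scoring tests.

The brute-force oracle enumerates every one-to-one assignment of theoretical
ions to peaks within tolerance and recomputes n, sum I_match and S_p from the
score definition directly; on small spectra the production matcher must agree
exactly.
"""

from itertools import permutations

import numpy as np
import pytest

import oligoms as om
from oligoms.chem import default_alphabet
from oligoms.library import ChargeTable, _make_entry
from oligoms.search import MgfError, consecutive_bonus, match_fragments
from oligoms.simulate import write_mgf


def entry_for(seq, **oligo_kw):
    ab = default_alphabet()
    return _make_entry(
        om.Oligo(seq, **oligo_kw),
        ChargeTable.default_precursor(),
        ChargeTable(((1, 10_000, (1,)),)),
        ab,
    )


def spectrum_from_entry(entry, charge=None, intensity=100.0, extra=()):
    charge = charge or min(entry.precursor_mz)
    mzs = [f.mz for f in entry.fragments] + [m for m, _ in extra]
    ints = [intensity] * len(entry.fragments) + [i for _, i in extra]
    return om.Spectrum("s1", entry.precursor_mz[charge], charge, np.array(mzs), np.array(ints))


class TestMgf:
    def test_round_trip_three_scans(self, tmp_path):
        rng = np.random.default_rng(1)
        spectra = [
            om.Spectrum(
                f"scan={i}", 500.0 + i, 2, rng.uniform(100, 900, 5), rng.uniform(1, 100, 5)
            )
            for i in range(3)
        ]
        path = tmp_path / "three.mgf"
        write_mgf(spectra, path)
        back = om.read_mgf(path)
        assert len(back) == 3
        assert [s.charge for s in back] == [2, 2, 2]
        np.testing.assert_allclose(back[0].mz, np.sort(spectra[0].mz), atol=1e-6)

    def test_negative_charge_dialect(self, tmp_path):
        path = tmp_path / "neg.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=t\nPEPMASS=400.2 999\nCHARGE=2-\n100.0 1\nEND IONS\n"
        )
        (s,) = om.read_mgf(path)
        assert s.charge == 2 and s.precursor_mz == pytest.approx(400.2)

    def test_missing_pepmass_names_scan(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nTITLE=broken_scan\n100.0 1\nEND IONS\n")
        with pytest.raises(MgfError, match="broken_scan"):
            om.read_mgf(path)

    def test_empty_peak_list_skipped_with_warning(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=e\nPEPMASS=400\nCHARGE=1-\nEND IONS\n"
            "BEGIN IONS\nTITLE=ok\nPEPMASS=400\nCHARGE=1-\n100 1\nEND IONS\n"
        )
        with pytest.warns(UserWarning):
            spectra = om.read_mgf(path)
        assert [s.scan_id for s in spectra] == ["ok"]

    def test_agrees_with_pyteomics_reader(self, tmp_path):
        """Cross-check our dialect against the pyteomics mgf parser."""
        from pyteomics import mgf as ptmgf

        rng = np.random.default_rng(4)
        spectra = [
            om.Spectrum("x", 650.31, 2, rng.uniform(100, 900, 8), rng.uniform(1, 100, 8))
        ]
        path = tmp_path / "pt.mgf"
        write_mgf(spectra, path)
        ours = om.read_mgf(path)[0]
        theirs = next(ptmgf.read(str(path)))
        np.testing.assert_allclose(ours.mz, theirs["m/z array"], atol=1e-6)
        np.testing.assert_allclose(ours.intensity, theirs["intensity array"], atol=1e-2)
        assert theirs["params"]["charge"][0] == -2


class TestPrecursorMatch:
    def test_exact_match_returned(self):
        e = entry_for("AUCG")
        s = spectrum_from_entry(e)
        assert om.match_precursor(s, [e], om.ScoreParams()) == [e]

    def test_out_of_tolerance_rejected(self):
        e = entry_for("AUCG")
        z = min(e.precursor_mz)
        mz = e.precursor_mz[z] * (1 + 50e-6)
        s = om.Spectrum("s", mz, z, np.array([100.0]), np.array([1.0]))
        assert om.match_precursor(s, [e], om.ScoreParams(ms1_ppm=20)) == []

    def test_isotopologue_flag_accepts_one_neutron_shift(self):
        e = entry_for("AUCG")
        z = min(e.precursor_mz)
        s = om.Spectrum(
            "s", e.precursor_mz[z] + 1.00336 / z, z, np.array([100.0]), np.array([1.0])
        )
        assert om.match_precursor(s, [e], om.ScoreParams()) == []
        assert om.match_precursor(s, [e], om.ScoreParams(match_isotopologues=True)) == [e]

    def test_wrong_charge_not_matched(self):
        e = entry_for("AUCG")
        z = min(e.precursor_mz)
        s = om.Spectrum("s", e.precursor_mz[z], z + 5, np.array([100.0]), np.array([1.0]))
        assert om.match_precursor(s, [e], om.ScoreParams()) == []


class TestFragmentMatch:
    def test_exact_theoretical_spectrum_matches_everything(self):
        e = entry_for("AUCGA")
        s = spectrum_from_entry(e)
        m = match_fragments(s, e, om.ScoreParams())
        assert m.n == m.L == len(e.fragments)
        assert m.sum_match == pytest.approx(m.sum_all)

    def test_loss_only_spectrum_scores_zero(self):
        e = entry_for("AUCG")
        losses = om.precursor_losses(e.oligo, charges=list(e.precursor_mz))
        mzs = np.array([f.mz for f in losses])
        s = om.Spectrum("s", e.precursor_mz[min(e.precursor_mz)], min(e.precursor_mz),
                        mzs, np.full(len(mzs), 50.0))
        m = match_fragments(s, e, om.ScoreParams())
        assert m.n == 0 and m.sum_all == 0.0
        assert om.score_sp(m, om.ScoreParams()) == 0.0

    def test_precursor_exclusion_window_removes_neighbors(self):
        e = entry_for("AUCG")
        z = min(e.precursor_mz)
        pmz = e.precursor_mz[z]
        # precursor peak plus a shoulder peak 1 m/z away: both excluded
        s = om.Spectrum("s", pmz, z,
                        np.array([pmz, pmz + 1.0, 300.0]), np.array([80.0, 70.0, 10.0]))
        m = match_fragments(s, e, om.ScoreParams(exclusion_window=1.5))
        assert len(m.excluded_peaks) == 2
        assert m.sum_all == pytest.approx(1.0)  # only the 300 m/z noise peak, normalized

    def test_tie_broken_toward_closer_then_stronger(self):
        e = entry_for("AUCG")
        ion = e.fragments[0]
        # two peaks equally close in m/z: the more intense one is taken
        s = om.Spectrum(
            "s", e.precursor_mz[1], 1,
            np.array([ion.mz * (1 - 5e-6), ion.mz * (1 + 5e-6)]),
            np.array([10.0, 90.0]),
        )
        m = match_fragments(s, e, om.ScoreParams(ms2_ppm=40))
        (matched_ion, pk, err) = next(
            a for a in m.assignments if a[0] is ion
        )
        assert s.intensity[pk] == 90.0

    def test_each_peak_used_once(self):
        e = entry_for("AUCGGA")
        s = spectrum_from_entry(e)
        m = match_fragments(s, e, om.ScoreParams())
        peaks = [pk for _, pk, _ in m.assignments]
        assert len(peaks) == len(set(peaks))


class TestScore:
    def test_full_match_with_zero_beta_scores_one(self):
        e = entry_for("AUCGA")
        s = spectrum_from_entry(e)
        m = match_fragments(s, e, om.ScoreParams())
        assert om.score_sp(m, om.ScoreParams(beta=0.0)) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """0.8 intensity fraction, 10 of 44 ions, 3 consecutive pairs in one
        series with beta=0.025, alpha=2 -> S_p = 0.2091."""
        from oligoms.search import MatchResult

        m = MatchResult(
            assignments=[], n=10, L=44, sum_match=0.8, sum_all=1.0,
            series_indices={"w": {1, 2, 3, 4}},  # 3 adjacent pairs
        )
        params = om.ScoreParams(beta=0.025, alpha=2.0)
        assert consecutive_bonus(m.series_indices, params) == pytest.approx(0.15)
        assert om.score_sp(m, params) == pytest.approx(0.2091, abs=2e-4)

    def test_consecutive_bonus_counts_within_series_only(self):
        params = om.ScoreParams(beta=0.025, alpha=2.0)
        # indices 1,2 in w and 3 in y: one adjacent pair total
        assert consecutive_bonus({"w": {1, 2}, "y": {3}}, params) == pytest.approx(0.05)
        # same indices all in one series: two adjacent pairs
        assert consecutive_bonus({"w": {1, 2, 3}}, params) == pytest.approx(0.10)

    def test_score_invariant_to_intensity_rescaling(self):
        e = entry_for("AUCGA")
        rng = np.random.default_rng(8)
        base = spectrum_from_entry(e, extra=[(m, 5.0) for m in rng.uniform(100, 300, 4)])
        scaled = om.Spectrum(
            base.scan_id, base.precursor_mz, base.charge, base.mz, base.intensity * 37.5
        )
        p = om.ScoreParams()
        s1 = om.score_sp(match_fragments(base, e, p), p)
        s2 = om.score_sp(match_fragments(scaled, e, p), p)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_score_monotone_in_added_correct_matches(self):
        e = entry_for("AUCGGA")
        p = om.ScoreParams()
        ions = sorted(e.fragments, key=lambda f: f.mz)
        noise = [(250.123, 40.0), (1900.456, 40.0)]
        scores = []
        for k in (3, 6, 12, len(ions)):
            extra = [(f.mz, 60.0) for f in ions[:k]] + noise
            s = om.Spectrum("s", e.precursor_mz[min(e.precursor_mz)], min(e.precursor_mz),
                            np.array([m for m, _ in extra]), np.array([i for _, i in extra]))
            scores.append(om.score_sp(match_fragments(s, e, p), p))
        assert scores == sorted(scores)
        assert scores[0] > 0

    def test_brute_force_assignment_oracle(self):
        """Exhaustive assignment enumeration reproduces n, sum I_match, S_p
        on small spectra (<= 6 peaks) against up to 3 candidates."""
        p = om.ScoreParams()
        rng = np.random.default_rng(23)
        candidates = [entry_for(s) for s in ("AUCG", "ACUG", "AGCU")]
        for trial in range(40):
            entry = candidates[rng.integers(0, 3)]
            pool = [f.mz for f in entry.fragments]
            k = int(rng.integers(1, 7))
            mzs, ints = [], []
            for _ in range(k):
                if rng.random() < 0.7:
                    mzs.append(float(rng.choice(pool)) * (1 + rng.normal(0, 5) * 1e-6))
                else:
                    mzs.append(float(rng.uniform(150, 1500)))
                ints.append(float(rng.uniform(1, 100)))
            s = om.Spectrum("s", entry.precursor_mz[1], 1, np.array(mzs), np.array(ints))
            for cand in candidates:
                m = match_fragments(s, cand, p)
                n_star, sum_star = _oracle_best_assignment(s, cand, p)
                assert m.n == n_star
                assert m.sum_match == pytest.approx(sum_star / _oracle_norm(s, cand, p))
                expected_sp = (
                    0.0
                    if m.n == 0 or m.sum_all == 0
                    else (m.sum_match / m.sum_all)
                    * (m.n / m.L)
                    * (1 + consecutive_bonus(m.series_indices, p))
                )
                assert om.score_sp(m, p) == pytest.approx(expected_sp)


def _oracle_excluded(s, entry, p):
    losses = om.precursor_losses(entry.oligo, charges=list(entry.precursor_mz))
    excluded = set()
    for ion in losses:
        for i, mz in enumerate(s.mz):
            if abs((mz - ion.mz) / ion.mz * 1e6) <= p.ms2_ppm:
                for j, mz2 in enumerate(s.mz):
                    if abs(mz2 - mz) <= p.exclusion_window:
                        excluded.add(j)
    return excluded


def _oracle_norm(s, entry, p):
    excluded = _oracle_excluded(s, entry, p)
    kept = [s.intensity[i] for i in range(len(s.mz)) if i not in excluded]
    return max(kept) if kept and max(kept) > 0 else 1.0


def _oracle_best_assignment(s, entry, p):
    """Exhaustively enumerate one-to-one assignments; return (n, sum I_match)
    of the optimum under (max matches, min total |ppm error|) — the objective
    the deterministic greedy matcher is meant to realize."""
    excluded = _oracle_excluded(s, entry, p)
    peaks = [i for i in range(len(s.mz)) if i not in excluded]
    compatible = {
        i: [
            (j, abs((s.mz[i] - f.mz) / f.mz * 1e6))
            for j, f in enumerate(entry.fragments)
            if abs((s.mz[i] - f.mz) / f.mz * 1e6) <= p.ms2_ppm
        ]
        for i in peaks
    }
    usable = [i for i in peaks if compatible[i]]
    best = (0, 0.0, 0.0)  # (count, -total_error, total_intensity)

    def recurse(idx, used_ions, count, err, total):
        nonlocal best
        if (count, -err, total) > best:
            best = (count, -err, total)
        if idx == len(usable):
            return
        i = usable[idx]
        recurse(idx + 1, used_ions, count, err, total)
        for j, e in compatible[i]:
            if j not in used_ions:
                recurse(idx + 1, used_ions | {j}, count + 1, err + e, total + s.intensity[i])

    recurse(0, frozenset(), 0, 0.0, 0.0)
    return best[0], best[2]


class TestRanking:
    def make_osms(self, scores, decoy_flags, seqs=None):
        from oligoms.search import MatchResult, OSM

        osms = []
        for i, (sp, dec) in enumerate(zip(scores, decoy_flags)):
            e = entry_for(seqs[i] if seqs else "AUCG")
            e.is_decoy = dec
            m = MatchResult([], n=5, L=33, sum_match=0.5, sum_all=1.0, series_indices={})
            osms.append(OSM("scan", e, m, sp))
        return osms

    def test_top_has_zero_delta(self):
        ranked = om.rank_and_delta(self.make_osms([1.0, 0.5], [False, False],
                                                  ["AUCG", "ACUG"]))
        assert ranked[0].delta_sp == 0.0 and ranked[0].rank == 1
        assert ranked[1].delta_sp == pytest.approx(0.5)

    def test_delta_spd_against_best_decoy(self):
        ranked = om.rank_and_delta(
            self.make_osms([1.0, 0.25], [False, True], ["AUCG", "ACUG"])
        )
        assert ranked[0].delta_spd == pytest.approx(0.75)

    def test_equal_scores_tiebreak_deterministic(self):
        ranked = om.rank_and_delta(
            self.make_osms([0.7, 0.7], [False, False], ["CAUG", "ACUG"])
        )
        assert [o.entry.sequence for o in ranked] == ["ACUG", "CAUG"]
        assert ranked[0].delta_sp2 == pytest.approx(0.0)

    def test_target_preferred_over_decoy_on_tie(self):
        ranked = om.rank_and_delta(
            self.make_osms([0.7, 0.7], [True, False], ["ACUG", "ACUG"])
        )
        assert not ranked[0].is_decoy

    def test_zero_top_score_flags_degenerate(self):
        ranked = om.rank_and_delta(self.make_osms([0.0, 0.0], [False, False],
                                                  ["AUCG", "ACUG"]))
        assert all(o.degenerate for o in ranked)
        assert all(o.delta_sp == 0.0 for o in ranked)

    def test_true_sequence_outranks_decoys_on_dominated_spectrum(self, toy_library):
        _, entries = toy_library
        params = om.SimParams(detection_p=0.95, noise_peaks=5)
        spectra, truth = om.synthesize_dataset(entries, 30, params, seed=99)
        osms = om.search(spectra, entries)
        frame = om.osm_frame(osms)
        rank1 = frame[frame["rank"] == 1].merge(truth, on="scan")
        assert not rank1["is_decoy"].any()
        assert (rank1["sequence_x"] == rank1["sequence_y"]).mean() >= 0.95
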