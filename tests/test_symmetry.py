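"""Selection rules, match conditions and phase schedules."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import symrec as sr
from symrec.symmetry import QuantumNumberError, _survives


def brute_force_terms(spec, interaction):
    """Independent oracle: exhaustive scan over (m, mu, Z) integers."""
    l, lam = sr.INTERACTIONS[interaction]
    found = set()
    zmax = 4 * (abs(spec.n) * l + spec.nu * lam) + 4
    for m in range(-l, l + 1):
        if l == 2 and m == 0:
            continue
        for mu in range(-lam, lam + 1):
            for z in range(-zmax, zmax + 1):
                if spec.kind == "R":
                    if (z - lam) % 2 == 0 and 2 * (m * spec.n - mu * spec.nu) == spec.N * z:
                        found.add((m, mu))
                else:
                    if m * spec.n - mu * spec.nu == spec.N * z:
                        found.add((m, mu))
    return found


@pytest.mark.parametrize(
    "N,n,nu,interaction,expected",
    [
        (18, 1, 7, "het_dipolar", {(2, -1), (-2, 1)}),
        (14, 8, 5, "het_dipolar", {(2, -1), (-2, 1)}),
        (14, 8, 5, "homo_dipolar", set()),
        (20, 9, 8, "het_dipolar", {(2, 1), (-2, -1)}),
    ],
)
def test_allowed_terms_known_sequences(N, n, nu, interaction, expected):
    spec = sr.SymmetrySpec(N=N, n=n, nu=nu)
    got = {(t.m, t.mu) for t in sr.allowed_terms(spec, interaction)}
    assert got == expected
    assert got == brute_force_terms(spec, interaction)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    N=st.integers(2, 15).map(lambda k: 2 * k),
    n=st.integers(1, 20),
    nu_frac=st.floats(0, 1),
    interaction=st.sampled_from(sorted(sr.INTERACTIONS)),
)
def test_allowed_terms_matches_brute_force(N, n, nu_frac, interaction):
    nu = int(nu_frac * (N // 2))
    spec = sr.SymmetrySpec(N=N, n=n, nu=nu)
    got = {(t.m, t.mu) for t in sr.allowed_terms(spec, interaction)}
    assert got == brute_force_terms(spec, interaction)
    # mirror symmetry of the rule
    assert got == {(-m, -mu) for m, mu in got}


def test_c_sequence_rule():
    # C7_2^1: classic homonuclear double-quantum sequence; the rule engine
    # must recouple (m, mu) with m*n - mu*nu = 0 mod 7
    spec = sr.SymmetrySpec(N=7, n=2, nu=1, kind="C")
    got = {(t.m, t.mu) for t in sr.allowed_terms(spec, "homo_dipolar")}
    assert got == brute_force_terms(spec, "homo_dipolar")
    assert (1, 2) in got and (-1, -2) in got


def test_invalid_quantum_numbers_raise():
    with pytest.raises(QuantumNumberError):
        sr.SymmetrySpec(N=15, n=8, nu=5)  # odd N for an R sequence
    with pytest.raises(QuantumNumberError):
        sr.SymmetrySpec(N=14, n=0, nu=5)
    with pytest.raises(QuantumNumberError):
        sr.SymmetrySpec(N=14, n=8, nu=8)  # nu > N/2
    with pytest.raises(QuantumNumberError):
        sr.allowed_terms(sr.SymmetrySpec(14, 8, 5), "quadrupolar")


class TestGammaEncoding:
    def test_single_m_per_mu(self):
        ts = sr.allowed_terms(sr.SymmetrySpec(14, 8, 5), "het_dipolar")
        assert sr.is_gamma_encoded(ts)

    def test_empty_set_is_not_encoded(self):
        assert not sr.is_gamma_encoded([])

    def test_both_signs_of_m_break_encoding(self):
        ts = [sr.HamTerm(2, 1, 1, 1), sr.HamTerm(2, -1, 1, 1)]
        assert not sr.is_gamma_encoded(ts)


class TestCorrelation:
    def test_anticorrelated(self):
        ts = sr.allowed_terms(sr.SymmetrySpec(14, 8, 5), "het_dipolar")
        assert sr.classify_correlation(ts) == "anticorrelated"

    def test_correlated(self):
        ts = sr.allowed_terms(sr.SymmetrySpec(20, 9, 8), "het_dipolar")
        assert sr.classify_correlation(ts) == "correlated"

    def test_mixed(self):
        ts = [sr.HamTerm(2, 2, 1, 1), sr.HamTerm(2, 2, 1, -1)]
        assert sr.classify_correlation(ts) == "mixed"

    def test_empty_raises(self):
        with pytest.raises(QuantumNumberError):
            sr.classify_correlation([])


class TestMatchField:
    def test_r18_1_7_is_nine_times_spinning(self):
        spec = sr.SymmetrySpec(18, 1, 7)
        assert sr.match_field(spec, 1, 60e3) == pytest.approx(540e3)
        assert sr.match_field(spec, 1, 10e3) == pytest.approx(90e3)

    def test_r14_8_5_base_and_composite(self, r14_8_5):
        assert sr.match_field(r14_8_5, 1, 60e3) == pytest.approx(52.5e3)
        f = sr.match_field(r14_8_5, float(sr.kp("1a", 115)), 60e3)
        assert f == pytest.approx(119.583e3, abs=1)

    def test_scales_linearly_with_spinning(self, r14_8_5):
        assert sr.match_field(r14_8_5, 1, 120e3) == 2 * sr.match_field(r14_8_5, 1, 60e3)


class TestEnumeration:
    def test_contains_known_candidate(self):
        recs = sr.enumerate_candidates((14, 14), (8, 8), 60e3,
                                       field_window=(0.1e3, 150e3))
        names = [r.spec.name for r in recs]
        assert "R14_8^5" in names
        rec = recs[names.index("R14_8^5")]
        assert rec.gamma_encoded and rec.correlation == "anticorrelated"
        assert rec.match_field_Hz == pytest.approx(52.5e3)

    def test_empty_window_is_empty(self):
        assert sr.enumerate_candidates((10, 42), (1, 37), 60e3,
                                       field_window=(0, 0)) == []

    def test_candidates_satisfy_all_criteria(self):
        recs = sr.enumerate_candidates((10, 20), (1, 20), 60e3,
                                       field_window=(0.1e3, 150e3))
        assert recs == sorted(recs, key=lambda r: (r.spec.N, r.spec.n, r.spec.nu))
        for r in recs:
            het = sr.allowed_terms(r.spec, "het_dipolar")
            assert het and sr.is_gamma_encoded(het)
            assert not sr.allowed_terms(r.spec, "homo_dipolar")
            assert 0.1e3 < r.match_field_Hz < 150e3

    def test_repeat_dedup(self):
        # R28_16^10 is two back-to-back R14_8^5 cycles: dropped by default
        with_dups = sr.enumerate_candidates((28, 28), (16, 16), 60e3,
                                            dedup_repeats=False)
        assert any(r.spec.nu == 10 for r in with_dups)
        primitive = sr.enumerate_candidates((28, 28), (16, 16), 60e3)
        assert not any(r.spec.nu == 10 for r in primitive)


class TestPhaseSchedule:
    def test_plain_pi_schedule(self, r14_8_5):
        sched = sr.phase_schedule(r14_8_5, "pi", 0, 60e3)
        assert len(sched.segments) == 14
        assert sched.total_duration == pytest.approx(8 / 60e3)
        for j, seg in enumerate(sched.segments):
            assert seg.duration == pytest.approx(8 / (14 * 60e3))
            want = (180 * 5 / 14) * (1 if j % 2 == 0 else -1)
            assert seg.rf_phase == pytest.approx(want)  # +/-64.29 deg

    def test_composite_segment_phases(self, r14_8_5):
        sched = sr.phase_schedule(r14_8_5, "1a", 115, 60e3)
        assert len(sched.segments) == 28
        base = 180 * 5 / 14
        # first element: 115 at base+0, 295 at base+180
        f0, f1 = sched.segments[0], sched.segments[1]
        assert f0.rf_phase == pytest.approx(base)
        assert f1.rf_phase == pytest.approx(base + 180)
        assert f0.duration * f0.rf_amplitude * 360 == pytest.approx(115)
        assert f1.duration * f1.rf_amplitude * 360 == pytest.approx(295)

    def test_nu_zero_means_no_alternation(self):
        sched = sr.phase_schedule(sr.SymmetrySpec(8, 3, 0), "pi", 0, 60e3)
        assert all(seg.rf_phase == 0 for seg in sched.segments)

    @pytest.mark.parametrize("element,theta", [("pi", 0), ("1a", 115),
                                               ("2a", 40), ("4a", 270)])
    def test_schedule_closure(self, r14_8_5, element, theta):
        """Total sweep = N*kp*180 deg and duration = n rotor periods."""
        sched = sr.phase_schedule(r14_8_5, element, theta, 60e3)
        sweep = sum(s.duration * s.rf_amplitude * 360 for s in sched.segments)
        kp = float(sr.kp(element, theta))
        assert sweep == pytest.approx(14 * kp * 180, rel=1e-12)
        assert sum(s.duration for s in sched.segments) == pytest.approx(
            sched.total_duration, rel=1e-12)
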