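"""Spin projection coefficients and effective hyperfine arithmetic."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oecspin import (
    HFCRecord,
    ValidationError,
    apply_mn_scaling,
    project_hfc,
    projection_coefficients,
    sort_and_ratio,
)
from oecspin.hfc_projection import ProjectionCoefficients

from conftest import make_cluster, random_cluster

HALF = Fraction(1, 2)


def dimer_ground_rho(s1: float, s2: float) -> tuple[float, float]:
    """Clebsch-Gordan closed form for the antiferromagnetic dimer ground
    state S = |s1 - s2|: rho_i = [S(S+1) + S_i(S_i+1) - S_j(S_j+1)] / [2S(S+1)].
    """
    S = abs(s1 - s2)
    d = 2 * S * (S + 1)
    return (
        (S * (S + 1) + s1 * (s1 + 1) - s2 * (s2 + 1)) / d,
        (S * (S + 1) + s2 * (s2 + 1) - s1 * (s1 + 1)) / d,
    )


class TestProjectionCoefficients:
    def test_lone_paramagnet_with_spectator_site(self):
        # S=1/2 site next to an S=0 site: the paramagnet carries everything
        cluster = make_cluster([HALF, Fraction(0)], {})
        rho = projection_coefficients(cluster)
        assert rho.rho == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_af_dimer_clebsch_gordan(self):
        cluster = make_cluster([Fraction(1), HALF], {(0, 1): -10.0})
        rho = projection_coefficients(cluster)
        assert rho.rho[0] == pytest.approx(4 / 3, abs=1e-10)
        assert rho.rho[1] == pytest.approx(-1 / 3, abs=1e-10)

    @given(
        s1=st.sampled_from([0.5, 1.0, 1.5, 2.0, 2.5]),
        s2=st.sampled_from([0.5, 1.0, 1.5, 2.0, 2.5]),
        J=st.floats(-40, -1),
    )
    @settings(max_examples=30, deadline=None)
    def test_af_dimer_matches_closed_form(self, s1, s2, J):
        if s1 == s2:
            return  # singlet ground state: no projection defined
        cluster = make_cluster(
            [Fraction(s1).limit_denominator(2), Fraction(s2).limit_denominator(2)],
            {(0, 1): J},
        )
        rho = projection_coefficients(cluster)
        expected = dimer_ground_rho(s1, s2)
        assert rho.rho[0] == pytest.approx(expected[0], abs=1e-8)
        assert rho.rho[1] == pytest.approx(expected[1], abs=1e-8)

    def test_singlet_ground_state_raises(self):
        cluster = make_cluster([HALF, HALF], {(0, 1): -10.0})
        with pytest.raises(ValidationError, match="singlet"):
            projection_coefficients(cluster)

    def test_normalization_on_random_clusters(self, rng):
        found = 0
        while found < 6:
            cluster = random_cluster(rng, n_sites=3)
            try:
                rho = projection_coefficients(cluster)
            except ValidationError:
                continue  # singlet ground state
            found += 1
            assert rho.total == pytest.approx(1.0, abs=1e-8)

    def test_rho_invariant_under_coupling_scaling(self, rng):
        cluster = random_cluster(rng, n_sites=3)
        try:
            base = projection_coefficients(cluster)
        except ValidationError:
            cluster = make_cluster([Fraction(1), HALF, HALF], {(0, 1): -7.0})
            base = projection_coefficients(cluster)
        scaled = make_cluster(
            cluster.spins, {p: 3.0 * J for p, J in cluster.couplings.items()}
        )
        other = projection_coefficients(scaled)
        assert other.rho == pytest.approx(base.rho, abs=1e-8)


class TestDoubletFixtures:
    def test_sign_patterns(self, bundle, doublet_names):
        """(+,-,-,+) for every doublet model except the closed-cubane outlier."""
        for name in doublet_names:
            rho = projection_coefficients(bundle.models[name])
            signs = tuple(1 if r > 0 else -1 for r in rho.rho)
            expected = (1, -1, 1, -1) if name == "D5" else (1, -1, -1, 1)
            assert signs == expected, name

    def test_normalization(self, bundle, doublet_names):
        for name in doublet_names:
            rho = projection_coefficients(bundle.models[name])
            assert rho.total == pytest.approx(1.0, abs=1e-8), name

    def test_magnitudes_within_reported_ranges(self, bundle, doublet_names):
        """|rho| windows: Mn1 1.07-1.99, Mn2/Mn3 0.45-1.25, Mn4 0.46-1.63.

        The near-degenerate A10 model computes rho1 = 1.008 and rho4 = 1.636
        from the printed (0.1-rounded) couplings; a sensitivity scan shows no
        coupling set consistent with the printed row reaches the reported
        bounds, so A10 is asserted with a 0.07 margin.
        """
        windows = [(1.07, 1.99), (0.45, 1.25), (0.45, 1.25), (0.46, 1.63)]
        for name in doublet_names:
            rho = projection_coefficients(bundle.models[name])
            margin = 0.07 if name == "A10" else 0.0
            for k, (lo, hi) in enumerate(windows):
                mag = abs(rho.rho[k])
                assert lo - margin <= mag <= hi + margin, (name, k + 1, mag)


class TestProjectHfc:
    def test_identity_projection(self):
        rho = ProjectionCoefficients(rho=(1.0,), M_S_used=HALF, total_spin=HALF)
        rec = HFCRecord(nucleus="Mn1", isotope="55Mn", alpha_iso=200.0, attached_site=0)
        assert project_hfc(rho, rec).A_iso_eff == pytest.approx(200.0)

    @pytest.mark.parametrize(
        "rho_val,alpha,expected",
        [(-1 / 3, 300.0, -100.0), (1.5, -150.0, -225.0)],
    )
    def test_sign_product(self, rho_val, alpha, expected):
        rho = ProjectionCoefficients(
            rho=(rho_val, 1 - rho_val), M_S_used=HALF, total_spin=HALF
        )
        rec = HFCRecord(nucleus="N", isotope="14N", alpha_iso=alpha, attached_site=0)
        out = project_hfc(rho, rec)
        assert out.A_iso_eff == pytest.approx(expected)
        assert out.A_iso_abs == pytest.approx(abs(expected))

    def test_missing_attached_site_raises(self):
        rho = ProjectionCoefficients(rho=(1.0,), M_S_used=HALF, total_spin=HALF)
        rec = HFCRecord(nucleus="O5", isotope="17O", alpha_iso=10.0)
        with pytest.raises(ValidationError, match="attached"):
            project_hfc(rho, rec)


class TestMnScaling:
    def test_factor_applied_to_mn(self):
        assert apply_mn_scaling(100.0) == pytest.approx(178.0)
        assert apply_mn_scaling(100.0, factor=1.0) == pytest.approx(100.0)

    def test_other_isotopes_pass_through_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="oecspin.hfc_projection"):
            out = apply_mn_scaling(5.0, isotope="14N")
        assert out == 5.0
        assert "not applied" in caplog.text


class TestSortAndRatio:
    def test_published_model_row(self):
        mags, ratios, sites = sort_and_ratio([188, 189, 216, 448], sites=[1, 2, 3, 4])
        assert mags == (448, 216, 189, 188)
        assert sites == (4, 3, 2, 1)
        assert tuple(round(r, 2) for r in ratios) == (2.07, 1.14, 1.01)

    def test_experimental_row(self):
        _, ratios, _ = sort_and_ratio([331, 231, 225, 186])
        assert tuple(round(r, 2) for r in ratios) == (1.43, 1.03, 1.21)

    def test_equal_values_and_tie_break_by_site(self):
        mags, ratios, sites = sort_and_ratio([5.0, 5.0, 5.0, 5.0], sites=[3, 1, 4, 2])
        assert ratios == (1.0, 1.0, 1.0)
        assert sites == (1, 2, 3, 4)  # ties resolved by ascending site

    def test_scale_invariance(self):
        _, base, _ = sort_and_ratio([448, 216, 189, 188])
        _, scaled, _ = sort_and_ratio([v * 1.78 for v in [448, 216, 189, 188]])
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError, match="4"):
            sort_and_ratio([1.0, 2.0, 3.0])

    def test_published_ratio_columns_reproduced(self, bundle):
        """Recomputed ratios vs the printed columns for descending rows.

        Printed ratios were evidently computed from unrounded couplings, so
        rows other than the exactly-matching examples are allowed one unit
        in the last printed digit (0.015).  The one row printed out of
        descending order is excluded: its printed ratios follow the printed
        (non-sorted) order and cannot result from any descending sort.
        """
        for name, row in bundle.mn_hfcs.items():
            if name == "A5":
                continue
            _, ratios, _ = sort_and_ratio(row["values"], row["sites"])
            printed = row["printed_ratios"]
            tol = 0.005 if name == "A4" else 0.015
            for r, p in zip(ratios, printed):
                assert round(r, 2) == pytest.approx(p, abs=tol), name
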