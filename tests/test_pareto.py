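import io
import math

import pytest

import codonfold as cf
from codonfold.design import DesignResult
from codonfold.pareto import (
    ParetoFront,
    filter_dominated,
    next_lambda,
    normalize_percentages,
    pareto_front,
)


def _pt(mfe, cai, cds="AUG", lam=0.5):
    l = max(len(cds) // 3, 1)
    S = l * math.log(cai)
    return DesignResult(
        cds=cds,
        structure="." * len(cds),
        mfe=mfe,
        S=S,
        cai=cai,
        objective_value=lam * mfe - (1 - lam) * S,
        lambda_used=lam,
        formulation="derna",
        exact=True,
    )


class TestNextLambda:
    def test_closed_form(self):
        lam = next_lambda((-10.0, -2.0), (-6.0, 0.0))
        assert lam == pytest.approx(1 / 3)
        # both points tie at lambda*
        assert lam * -10 - (1 - lam) * -2 == pytest.approx(lam * -6 - (1 - lam) * 0)
        assert lam * -10 - (1 - lam) * -2 == pytest.approx(-2.0)

    def test_identical_points_raise(self):
        with pytest.raises(ValueError, match="identical"):
            next_lambda((-5.0, -1.0), (-5.0, -1.0))

    def test_degenerate_closes_interval(self):
        assert next_lambda((-5.0, -1.0), (-5.0, 0.0)) is None
        assert next_lambda((-7.0, -1.0), (-5.0, -1.0)) is None

    def test_wrong_orientation_rejected(self):
        with pytest.raises(ValueError):
            next_lambda((-6.0, 0.0), (-10.0, -2.0))


class TestFilterDominated:
    def test_dominated_point_removed(self):
        pts = [
            _pt(-10.0, 0.80, "AAAAAA"),
            _pt(-9.0, 0.85, "CCCCCC"),
            _pt(-8.0, 0.70, "GGGGGG"),  # dominated by (-9, 0.85)
        ]
        kept = filter_dominated(pts)
        assert [p.cds for p in kept] == ["AAAAAA", "CCCCCC"]
        assert [p.cai for p in kept] == sorted(p.cai for p in kept)

    def test_single_point_unchanged(self):
        pts = [_pt(-5.0, 0.9)]
        assert filter_dominated(pts) == pts

    def test_duplicate_cds_collapsed(self):
        pts = [_pt(-5.0, 0.9, "AUGAUG"), _pt(-5.0, 0.9, "AUGAUG")]
        assert len(filter_dominated(pts)) == 1


class TestNormalizePercentages:
    def _front(self, *pts):
        return ParetoFront(points=tuple(pts), raw=tuple(pts), n=len(pts), N=len(pts))

    def test_endpoints_and_midpoint(self):
        f = normalize_percentages(
            self._front(
                _pt(-20.0, 0.8, "AAA"), _pt(-16.25, 0.9, "CCC"), _pt(-12.5, 1.0, "GGG")
            )
        )
        assert f.mfe_pct == pytest.approx((100.0, 50.0, 0.0))
        assert f.cai_pct == pytest.approx((0.0, 50.0, 100.0))

    def test_single_point_convention(self):
        f = normalize_percentages(self._front(_pt(-3.0, 0.9)))
        assert f.mfe_pct == (100.0,) and f.cai_pct == (100.0,)

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            normalize_percentages(self._front())


class TestParetoFront:
    def test_single_cds_protein(self, human_w, nus):
        front = pareto_front("MW", human_w, nus)
        assert front.n == 1 and len(front.points) == 1
        assert front.points[0].cds == "AUGUGG"
        assert front.N >= 2  # both endpoint solves counted

    def test_small_protein_front_properties(self, human_w, nus):
        from codonfold.oracle import design_profile

        prot = "MFLS"
        front = pareto_front(prot, human_w, nus)
        profile = design_profile(prot, human_w, nus)
        assert 1 <= front.n <= front.N
        cais = [p.cai for p in front.points]
        mfes = [p.mfe for p in front.points]
        assert cais == sorted(cais)
        assert all(mfes[i] < mfes[i + 1] for i in range(len(mfes) - 1))
        for p in front.points:
            lam = p.lambda_used
            best = min(lam * m - (1 - lam) * S for _, m, S in profile)
            assert lam * p.mfe - (1 - lam) * p.S == pytest.approx(best, abs=1e-9)

    def test_tsv_one_row_per_distinct_cds(self, human_w, nus):
        front = pareto_front("MW", human_w, nus)
        buf = io.StringIO()
        front.to_tsv(buf)
        lines = buf.getvalue().strip().splitlines()
        assert len(lines) == 2  # header + 1 distinct CDS
        assert lines[1].endswith("\t1")

    def test_rerun_identical(self, human_w, nus):
        f1 = pareto_front("MLKS", human_w, nus)
        f2 = pareto_front("MLKS", human_w, nus)
        assert [(p.cds, p.structure, p.lambda_used) for p in f1.points] == [
            (p.cds, p.structure, p.lambda_used) for p in f2.points
        ]
        assert (f1.n, f1.N) == (f2.n, f2.N)
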