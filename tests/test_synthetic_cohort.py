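"""Synthetic cohort generator: determinism, planted structure, caller noise."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from conftest import small_slide_params, tiny_cohort_params
from neocorr.errors import ParameterError
from neocorr.response_scoring import compute_ptr
from neocorr.synthetic_cohort import (
    CallerNoiseParams,
    CohortParams,
    SlidePatternParams,
    SomaticVariant,
    generate_caller_callsets,
    generate_cell_slide,
    generate_patient_cohort,
)
from neocorr.neoepitope_pipeline import ProteinConsequence
from neocorr.variant_consensus import SNV_CALLERS, VariantKey


def ki67_treg_distances(cells):
    """Nearest-Treg distance per Ki67 status for FoxP3- T cells."""
    tcell = cells[cells["phenotype"].isin(["CD8 T cell", "CD4 T cell"])]
    tregs = cells[cells["phenotype"] == "Treg"][["x_um", "y_um"]].to_numpy()
    tree = cKDTree(tregs)
    d, _ = tree.query(tcell[["x_um", "y_um"]].to_numpy())
    ki67 = tcell["ki67"].to_numpy(dtype=bool)
    return d[ki67], d[~ki67]


class TestGenerateCellSlide:
    def test_cells_inside_field_and_marker_consistency(self):
        params = small_slide_params()
        sample = generate_cell_slide(params, 0)
        c = sample.cells
        assert ((c.x_um >= 0) & (c.x_um <= params.field_width_um)).all()
        assert ((c.y_um >= 0) & (c.y_um <= params.field_height_um)).all()
        # tumor cells CK+, immune cells CK-
        assert c.loc[c.phenotype == "Tumor cell", "ck"].all()
        assert not c.loc[c.phenotype != "Tumor cell", "ck"].any()
        assert set(c.intensity_bin) <= {0, 1, 2, 3}
        assert (c.diameter_um > 0).all()
        assert set(c.compartment) <= {"tumor", "stroma"}

    def test_exclusion_radius_enforced(self):
        sample = generate_cell_slide(small_slide_params(treg_exclusion_radius_um=40.0), 1)
        d_pos, _ = ki67_treg_distances(sample.cells)
        assert d_pos.min() >= 40.0

    def test_zero_radius_gives_exchangeable_ki67_classes(self):
        # with no exclusion, nearest-Treg distances are indistinguishable
        pooled_pos, pooled_neg = [], []
        for seed in range(6):
            sample = generate_cell_slide(
                small_slide_params(treg_exclusion_radius_um=0.0), seed
            )
            d_pos, d_neg = ki67_treg_distances(sample.cells)
            pooled_pos.append(d_pos)
            pooled_neg.append(d_neg)
        d_pos = np.concatenate(pooled_pos)
        d_neg = np.concatenate(pooled_neg)
        assert stats.ks_2samp(d_pos, d_neg).pvalue > 0.01
        assert abs(d_pos.mean() - d_neg.mean()) < 0.1 * d_neg.mean()

    def test_counts_follow_poisson_intensity(self):
        # 1 mm^2 pure stroma, Treg density 50/mm^2 -> count in the 99% interval
        params = SlidePatternParams(
            field_width_um=1000.0, field_height_um=1000.0, tumor_nest_count=0,
            stromal_densities={"CD8 T cell": 0.0, "CD4 T cell": 0.0, "Treg": 50.0,
                               "PMN": 0.0, "Macrophage": 0.0},
            intratumoral_densities={p: 0.0 for p in
                                    ("CD8 T cell", "CD4 T cell", "Treg", "PMN", "Macrophage")},
            treg_exclusion_radius_um=0.0,
        )
        n = (generate_cell_slide(params, 4).cells["phenotype"] == "Treg").sum()
        lo, hi = stats.poisson.ppf([0.005, 0.995], 50)
        assert lo <= n <= hi

    def test_determinism(self):
        a = generate_cell_slide(small_slide_params(), 9).cells
        b = generate_cell_slide(small_slide_params(), 9).cells
        assert a.equals(b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tumor_cell_density": -5.0},
            {"tumor_cell_density": float("nan")},
            {"ki67_fraction_tcell": 1.5},
            {"treg_exclusion_radius_um": -1.0},
            {"intensity_bin_probs": (0.5, 0.5, 0.5, 0.5)},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ParameterError):
            small_slide_params(**kwargs)


def make_truth(n, rng=None, snv=True):
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(n):
        if snv:
            key = VariantKey(f"chr{i % 22 + 1}", 1000 + i, "A", "T")
        else:
            key = VariantKey(f"chr{i % 22 + 1}", 1000 + i, "AT", "A")
        cons = ProteinConsequence("missense", 1, "A", "C")
        out.append(SomaticVariant(key, 0.3, "G001", cons))
    return out


class TestCallerCallsets:
    def test_perfect_sensitivity_all_supported(self):
        noise = CallerNoiseParams(
            sensitivity={c: 1.0 for c in SNV_CALLERS},
            false_call_mean={c: 0.0 for c in SNV_CALLERS},
        )
        truth = make_truth(50)
        snv_sets, _ = generate_caller_callsets(truth, noise, 0)
        for cs in snv_sets.values():
            assert set(cs.calls) == {v.key for v in truth}

    def test_zero_sensitivity_all_empty(self):
        noise = CallerNoiseParams(
            sensitivity={c: 0.0 for c in SNV_CALLERS},
            false_call_mean={c: 0.0 for c in SNV_CALLERS},
        )
        snv_sets, indel_sets = generate_caller_callsets(make_truth(30), noise, 0)
        assert all(len(cs.calls) == 0 for cs in snv_sets.values())
        assert all(len(cs.calls) == 0 for cs in indel_sets.values())

    def test_muse_receives_no_indels(self):
        noise = CallerNoiseParams(
            sensitivity={c: 1.0 for c in SNV_CALLERS},
            false_call_mean={c: 0.0 for c in SNV_CALLERS},
        )
        snv_sets, indel_sets = generate_caller_callsets(make_truth(20, snv=False), noise, 0)
        assert "MuSE" not in indel_sets
        assert all(k.is_snv for k in snv_sets["MuSE"].calls)

    def test_duplicate_truth_rejected(self):
        truth = make_truth(2)
        truth[1] = SomaticVariant(truth[0].key, 0.2, "G001", truth[0].consequence)
        with pytest.raises(ParameterError):
            generate_caller_callsets(truth, CallerNoiseParams(), 0)

    def test_bad_sensitivity_rejected(self):
        with pytest.raises(ParameterError):
            CallerNoiseParams(sensitivity={c: 1.2 for c in SNV_CALLERS})


class TestGeneratePatientCohort:
    def test_exact_responder_count_and_ptr_threshold(self, tiny_cohort):
        responders = [p for p in tiny_cohort.patients if p.planted_responder]
        assert len(responders) == 3  # round(6 * 0.5)
        for p in tiny_cohort.patients:
            ptr = compute_ptr([s for s in p.slide_areas if s.site == "primary"])
            assert (ptr >= 50) == p.planted_responder

    def test_zero_responder_fraction(self):
        cohort = generate_patient_cohort(
            tiny_cohort_params(n_patients=3, responder_fraction=0.0, seed=5)
        )
        assert cohort.planted_responders == set()
        for p in cohort.patients:
            assert compute_ptr([s for s in p.slide_areas if s.site == "primary"]) < 50

    def test_determinism_byte_identical_output(self, tmp_path):
        params = tiny_cohort_params(n_patients=2, seed=21)
        generate_patient_cohort(params).write(tmp_path / "a")
        generate_patient_cohort(params).write(tmp_path / "b")
        files_a = sorted(f.relative_to(tmp_path / "a") for f in (tmp_path / "a").rglob("*")
                         if f.is_file())
        files_b = sorted(f.relative_to(tmp_path / "b") for f in (tmp_path / "b").rglob("*")
                         if f.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_invalid_cohort_params(self):
        with pytest.raises(ParameterError):
            CohortParams(n_patients=0)
        with pytest.raises(ParameterError):
            CohortParams(responder_fraction=1.5)

    def test_patients_carry_complete_modalities(self, tiny_cohort):
        for p in tiny_cohort.patients:
            assert len(p.cells_pre) and len(p.cells_post)
            assert p.slide_areas and p.lesions
            assert set(p.snv_callsets) == set(SNV_CALLERS)
            assert p.hla_alleles and p.tpm
            assert p.pretreatment_keys <= {v.key for v in p.truth_variants}
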