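import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hcineq.schema as schema
from hcineq import (GeneratorConfig, detect_duplicates,
                    endorsement_probability_from_or, generate_cohort,
                    plant_duplicates, read_cohort, write_cohort)
from hcineq.catalog import ItemCatalog, Item


def tiny_catalog(n_items=1, p_section="sensory"):
    items = tuple(
        Item(id=f"it{i}", section=p_section, text="", endorse_is_negative=True,
             in_score=True)
        for i in range(n_items))
    return ItemCatalog(items=items, situations=())


class TestEndorsementProbability:
    @pytest.mark.parametrize("p0,or_target,expected", [
        (0.5, 1.0, 0.5),            # OR=1 leaves the rate unchanged
        (0.2, 4.0, 0.5),            # odds 0.25 -> 1.0
        (0.7638, 0.365, 0.5414),    # published control rate + OR recovers
                                    # the published case endorsement rate
    ])
    def test_known_values(self, p0, or_target, expected):
        assert endorsement_probability_from_or(p0, or_target) == pytest.approx(
            expected, abs=5e-4)

    @pytest.mark.parametrize("p0,or_target", [
        (0.0, 1.0), (1.0, 1.0), (-0.1, 1.0), (0.5, 0.0), (0.5, -2.0)])
    def test_invalid_parameters(self, p0, or_target):
        with pytest.raises(ValueError):
            endorsement_probability_from_or(p0, or_target)

    @given(p0=st.floats(0.01, 0.99), or_target=st.floats(0.05, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_inverts_odds_ratio(self, p0, or_target):
        p1 = endorsement_probability_from_or(p0, or_target)
        odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio == pytest.approx(or_target, rel=1e-9)


class TestGenerateCohort:
    def test_null_config_plain_records(self):
        cfg = GeneratorConfig(
            n_case=10, n_control=10, n_duplicates=0, n_incomplete=0,
            n_unconfirmed=0, item_missing_rate=0.0,
            covariate_missing_rates={}, seed=1,
            item_effects={"it0": (0.5, 1.0)}, shutdown_effects={},
            meltdown_effects={}, condition_effects={},
            catalog=tiny_catalog())
        bundle = generate_cohort(cfg)
        assert len(bundle.frame) == 20
        assert bundle.manifest.duplicates == []
        assert bundle.frame["item_it0"].notna().all()

    def test_planted_counts_exact(self, small_bundle):
        m, cfg = small_bundle.manifest, small_bundle.config
        assert len(m.duplicates) == cfg.n_duplicates
        assert len(m.incomplete) == cfg.n_incomplete
        assert len(m.unconfirmed) == cfg.n_unconfirmed
        assert len(small_bundle.frame) == (
            cfg.n_case + cfg.n_control + cfg.n_duplicates
            + cfg.n_incomplete + cfg.n_unconfirmed)

    def test_case_rate_converges_to_planted_or(self):
        cfg = GeneratorConfig(
            n_case=5000, n_control=5000, n_duplicates=0, n_incomplete=0,
            n_unconfirmed=0, item_missing_rate=0.0, covariate_missing_rates={},
            item_effects={"it0": (0.2, 4.0)}, shutdown_effects={},
            meltdown_effects={}, condition_effects={}, seed=7,
            catalog=tiny_catalog())
        frame = generate_cohort(cfg).frame
        cases = frame[frame[schema.AUTISM_DIAGNOSIS] == "yes"].head(5000)
        rate = cases["item_it0"].isin(schema.LIKERT_ENDORSE).mean()
        assert 0.47 <= rate <= 0.53

    def test_missingness_rates_close_to_configured(self):
        cfg = GeneratorConfig(n_case=5000, n_control=5000, n_duplicates=0,
                              n_incomplete=0, n_unconfirmed=0, seed=3)
        frame = generate_cohort(cfg).frame
        for cov, target in cfg.covariate_missing_rates.items():
            assert frame[cov].isna().mean() == pytest.approx(target, abs=0.02)
        miss = frame["item_ax_setup"].isna().mean()
        assert miss == pytest.approx(cfg.item_missing_rate, abs=0.02)

    def test_same_seed_byte_identical(self):
        cfg = dict(n_case=80, n_control=90, n_duplicates=3, n_incomplete=4,
                   n_unconfirmed=2, seed=99)
        buffers = []
        for _ in range(2):
            buf = io.StringIO()
            generate_cohort(GeneratorConfig(**cfg)).frame.to_csv(buf, index=False)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]

    def test_other_sex_only_in_case_group(self, small_bundle):
        frame = small_bundle.frame
        other = frame[frame[schema.SEX_AT_BIRTH] == "Other"]
        assert (other[schema.AUTISM_DIAGNOSIS] == "yes").all()

    def test_extras_exceeding_core_rejected(self):
        cfg = GeneratorConfig(n_case=5, n_control=5, n_duplicates=20,
                              n_incomplete=0, n_unconfirmed=0)
        with pytest.raises(ValueError, match="planted extras"):
            generate_cohort(cfg)

    def test_incomplete_records_have_no_section_answers(self, small_bundle, catalog):
        frame = small_bundle.frame
        inc = frame[frame[schema.PID].isin(small_bundle.manifest.incomplete)]
        for it in catalog.scored_items():
            assert inc[schema.item_col(it.id)].isna().all()
        for sid in catalog.situations:
            assert not inc[schema.shutdown_col(sid)].any()
            assert not inc[schema.meltdown_col(sid)].any()


class TestEffectCalibration:
    def test_empirical_or_within_wald_ci_of_planted(self):
        """Across seeded replicates the empirical cross-product OR covers
        the planted OR through its own 95% Wald CI in >= 90% of runs."""
        z = 1.959963984540054
        covered = 0
        reps = 40
        for seed in range(reps):
            cfg = GeneratorConfig(
                n_case=5000, n_control=5000, n_duplicates=0, n_incomplete=0,
                n_unconfirmed=0, item_missing_rate=0.0,
                covariate_missing_rates={},
                item_effects={"it0": (0.3, 2.5)}, shutdown_effects={},
                meltdown_effects={}, condition_effects={}, seed=seed,
                catalog=tiny_catalog())
            frame = generate_cohort(cfg).frame
            case = frame[schema.AUTISM_DIAGNOSIS] == "yes"
            endorsed = frame["item_it0"].isin(schema.LIKERT_ENDORSE)
            a = (case & endorsed).sum()
            b = (case & ~endorsed).sum()
            c = (~case & endorsed).sum()
            d = (~case & ~endorsed).sum()
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            log_or = np.log(a * d / (b * c))
            covered += abs(log_or - np.log(2.5)) <= z * se
        assert covered / reps >= 0.9


class TestPlantDuplicates:
    def test_zero_is_noop(self, small_bundle):
        frame = small_bundle.frame
        out, manifest = plant_duplicates(frame, 0, seed=1)
        assert out is frame and manifest == []

    def test_count_bookkeeping(self, small_bundle):
        frame = small_bundle.frame.head(10)
        out, manifest = plant_duplicates(frame, 3, seed=1)
        assert len(out) == 13 and len(manifest) == 3
        assert set(manifest).isdisjoint(frame[schema.PID])

    def test_too_many_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="cannot plant"):
            plant_duplicates(small_bundle.frame.head(4), 5, seed=0)

    def test_planted_set_is_exactly_what_detector_flags(self):
        cfg = GeneratorConfig(n_case=240, n_control=240, n_duplicates=20,
                              n_incomplete=0, n_unconfirmed=0, seed=13)
        bundle = generate_cohort(cfg)
        flagged = detect_duplicates(bundle.frame)
        assert flagged == set(bundle.manifest.duplicates)


def test_cohort_csv_round_trip(tmp_path, small_bundle):
    path = tmp_path / "cohort.csv"
    write_cohort(small_bundle.frame, path)
    back = read_cohort(path)
    assert len(back) == len(small_bundle.frame)
    assert back[schema.CONSENTED].dtype == bool
    orig = small_bundle.frame
    assert list(back[schema.PID]) == list(orig[schema.PID])
    assert np.allclose(back[schema.AGE], orig[schema.AGE])
    assert (back["item_ax_setup"].fillna("NA") ==
            orig["item_ax_setup"].fillna("NA")).all()


def test_config_yaml_round_trip(tmp_path):
    cfg = GeneratorConfig(n_case=12, n_control=13, seed=5)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back.n_case == 12 and back.seed == 5
    assert back.item_effects == dict(cfg.item_effects)
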