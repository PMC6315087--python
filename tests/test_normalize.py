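import numpy as np
import pandas as pd
import pytest

from xspecies_expr.datamodel import ExpressionMatrix
from xspecies_expr.normalize import (
    apply_weighting,
    compute_weighting_factors,
    normalize_expression,
    preprocess_replicates,
    select_reference_orthologs,
)

from conftest import make_matrix


def triplicate_matrix(rep_values):
    """One species x two tissues x three replicates; same triplet everywhere."""
    n_t = len(rep_values[0]) if np.ndim(rep_values) > 1 else 1
    vals = np.atleast_2d(rep_values)
    cols, meta_rows = [], []
    data = []
    for ti in ("MAG", "TESTIS"):
        for r in range(1, 4):
            cols.append(f"sp1_{ti}_{r}")
            meta_rows.append((f"sp1_{ti}_{r}", "sp1", ti, r))
    arr = np.tile(vals, (1, 2))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "species", "tissue", "replicate"])
    ids = [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(pd.DataFrame(arr, index=ids, columns=cols), meta.set_index("sample_id"))


class TestPreprocessReplicates:
    @pytest.mark.parametrize(
        "reps,expected",
        [((0, 0, 0), 0.0), ((1, 1, 1), 1.0), ((2, 4, 6), np.log2(5.0))],
    )
    def test_replicate_mean_then_log(self, reps, expected):
        m = triplicate_matrix([list(reps)])
        p = preprocess_replicates(m)
        assert p.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert p.is_log
        assert len(p.sample_ids) == 2  # one column per (species, tissue)

    def test_rejects_log_input(self):
        m = make_matrix([[1.0, 2.0]], is_log=True)
        with pytest.raises(ValueError, match="linear"):
            preprocess_replicates(m)


class TestSelectReferenceOrthologs:
    def test_distinct_constant_transcripts(self):
        # 12 transcripts, each constant across samples, distinct levels:
        # identical ranks everywhere -> variance 0; IQR keeps the 6 middle
        # median ranks; the tertile keeps 2 (ties broken by id).
        levels = np.arange(1.0, 13.0)
        vals = np.tile(levels[:, None], (1, 4))
        m = make_matrix(vals, species=["s1", "s2"], is_log=True)
        refs = select_reference_orthologs(m)
        assert len(refs) == 2
        # survivors of the IQR cut are ranks 4..9 -> g4..g9; first two by id
        assert refs == ["g4", "g5"]

    def test_top_expressed_everywhere_removed(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 5, size=(12, 4))
        vals[0, :] = 100.0  # top rank in every sample
        m = make_matrix(vals, species=["s1", "s2"], is_log=True)
        assert "g1" not in select_reference_orthologs(m)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 8, size=(40, 10))
        m = make_matrix(vals, species=[f"s{i}" for i in range(5)], is_log=True)
        base = select_reference_orthologs(m)
        for rep in range(20):
            t = vals.copy()
            for j in range(t.shape[1]):
                a = rng.uniform(0.5, 3.0)
                b = rng.uniform(-1.0, 1.0)
                p = rng.uniform(0.5, 2.0)
                t[:, j] = a * (t[:, j] + 0.5) ** p + b  # strictly increasing
            m2 = make_matrix(t, species=[f"s{i}" for i in range(5)], is_log=True)
            assert select_reference_orthologs(m2) == base

    def test_too_few_orthologs_errors(self):
        m = make_matrix(np.ones((3, 4)), species=["s1", "s2"], is_log=True)
        with pytest.raises(ValueError, match="too few"):
            select_reference_orthologs(m)


class TestComputeWeightingFactors:
    def test_identical_samples_give_unit_factors(self):
        vals = np.tile(np.arange(1.0, 9.0)[:, None], (1, 4))
        m = make_matrix(vals, species=["s1", "s2"], is_log=True)
        w = compute_weighting_factors(m, [f"g{i}" for i in range(1, 9)])
        np.testing.assert_allclose(w.factors.to_numpy(), 1.0)

    def test_two_sample_hand_computation(self):
        # sample2 = 1.2 x sample1 -> medians m, 1.2m -> factors m/1.1m, 1.2m/1.1m
        base = np.arange(1.0, 9.0)
        vals = np.column_stack([base, 1.2 * base])
        m = make_matrix(vals, species=["s1"], is_log=True)
        w = compute_weighting_factors(m, [f"g{i}" for i in range(1, 9)])
        np.testing.assert_allclose(
            w.factors.to_numpy(), [1 / 1.1, 1.2 / 1.1], rtol=1e-12
        )

    def test_factors_average_to_one(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 10, size=(20, 10))
        m = make_matrix(vals, species=[f"s{i}" for i in range(5)], is_log=True)
        w = compute_weighting_factors(m, m.transcript_ids[:10])
        assert w.factors.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_global_mean_errors(self):
        m = make_matrix(np.zeros((4, 2)), species=["s1"], is_log=True)
        with pytest.raises(ValueError, match="global mean"):
            compute_weighting_factors(m, m.transcript_ids)


class TestApplyWeighting:
    def test_unit_factors_are_identity(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 10, size=(10, 4))
        m = make_matrix(vals, species=["s1", "s2"], is_log=True)
        w = compute_weighting_factors(m, m.transcript_ids)
        w.factors[:] = 1.0
        out = apply_weighting(m, w)
        np.testing.assert_array_equal(out.values.to_numpy(), vals)

    def test_reference_medians_equalised(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 10, size=(30, 10)) * rng.uniform(0.5, 2.0, size=10)
        m = make_matrix(vals, species=[f"s{i}" for i in range(5)], is_log=True)
        refs = select_reference_orthologs(m)
        w = compute_weighting_factors(m, refs)
        out = apply_weighting(m, w)
        medians = out.values.loc[refs].median(axis=0)
        assert medians.max() - medians.min() <= 1e-9
        assert medians.iloc[0] == pytest.approx(w.global_mean, abs=1e-9)

    def test_literal_multiply_moves_medians_apart(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(1, 10, size=(30, 4)) * np.array([0.6, 1.0, 1.4, 1.8])
        m = make_matrix(vals, species=["s1", "s2"], is_log=True)
        refs = select_reference_orthologs(m)
        w = compute_weighting_factors(m, refs)
        lit = apply_weighting(m, w, literal_multiply=True)
        med = lit.values.loc[refs].median(axis=0)
        assert med.max() - med.min() > 1e-6


def test_end_to_end_distortion_recovery():
    """Planted per-condition linear-scale distortions are estimated by the
    weighting factors: the estimated corrective factor 1/f tracks the true
    corrective factor 1/c almost perfectly when there is no noise."""
    from xspecies_expr.simulate import SimulationConfig, simulate_dataset

    rng = np.random.default_rng(1)
    conds = [(sp, ti) for sp in
             ["arabiensis", "coluzzii", "gambiae", "merus", "quadriannulatus"]
             for ti in ("MAG", "TESTIS")]
    c = {cond: float(np.exp(rng.uniform(np.log(0.5), np.log(2)))) for cond in conds}
    factors = {f"{sp}_{ti}_{r}": c[(sp, ti)] for sp, ti in conds for r in (1, 2, 3)}
    cfg = SimulationConfig(
        seed=1, n_transcripts=1000, replicate_noise_sd_log2=0.0,
        frac_tissue_enriched=0.0, frac_lineage_dependent=0.0,
        frac_highly_variable=0.0, sample_scale_factors=factors,
    )
    m, truth, _, _ = simulate_dataset(cfg)
    _, _, w = normalize_expression(m)
    est = np.array([w.factor_for(sp, ti) for sp, ti in conds])
    true = np.array([c[cond] for cond in conds])
    r = np.corrcoef(1.0 / est, 1.0 / true)[0, 1]
    assert r > 0.99
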