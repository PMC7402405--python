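"""Profile bigram, flattening rules and 456-dim vector assembly."""

import numpy as np
import pytest

import phoglysite as pg
from phoglysite.features import profile_bigram, flatten_bigram, flatten_structural


def bigram_reference(M):
    """Literal double-loop transcription of the bigram definition."""
    M = np.asarray(M, dtype=float)
    B = np.zeros((20, 20))
    for p in range(20):
        for q in range(20):
            B[p, q] = sum(
                M[k, p] * M[k + 1, q] for k in range(M.shape[0] - 1)
            )
    return B


def random_row_stochastic(rng, rows=41):
    m = rng.dirichlet(np.ones(20), size=rows)
    return m / m.sum(axis=1, keepdims=True)


def test_bigram_one_hot_rows():
    M = np.zeros((41, 20))
    M[:, 0] = 1.0
    B = profile_bigram(M).B
    assert B[0, 0] == 40.0
    assert B.sum() == 40.0
    assert np.count_nonzero(B) == 1


def test_bigram_uniform_rows_closed_form():
    M = np.full((41, 20), 0.05)
    B = profile_bigram(M).B
    np.testing.assert_allclose(B, 0.1)  # 40 * 0.05 * 0.05
    np.testing.assert_allclose(B.sum(), 40.0)


def test_bigram_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        M = random_row_stochastic(rng)
        np.testing.assert_allclose(
            profile_bigram(M).B, bigram_reference(M), atol=1e-12, rtol=0
        )


def test_bigram_mass_conservation():
    rng = np.random.default_rng(8)
    for rows in (2, 5, 41):
        M = random_row_stochastic(rng, rows=rows)
        np.testing.assert_allclose(
            profile_bigram(M).B.sum(), rows - 1, atol=1e-9
        )


def test_bigram_permutation_covariance():
    """Permuting profile columns permutes bigram rows and columns alike."""
    rng = np.random.default_rng(9)
    M = random_row_stochastic(rng)
    perm = rng.permutation(20)
    B = profile_bigram(M).B
    B_perm = profile_bigram(M[:, perm]).B
    np.testing.assert_allclose(B_perm, B[np.ix_(perm, perm)], atol=1e-12)


def test_bigram_requires_two_rows():
    with pytest.raises(ValueError, match="2 rows"):
        profile_bigram(np.full((1, 20), 0.05))


def test_flatten_bigram_p_major_order():
    B = np.zeros((20, 20))
    B[0, 1] = 0.7
    F = flatten_bigram(pg.BigramMatrix(B=B, source_rows=41))
    assert F[1] == 0.7  # entry 20*(p-1)+q, 1-based -> index 1
    assert np.count_nonzero(F) == 1


def test_flatten_bigram_diagonal_positions():
    F = flatten_bigram(pg.BigramMatrix(B=np.eye(20), source_rows=41))
    # nonzeros at 1-based positions 20*(p-1)+p: 1, 22, 43, ... 400
    assert np.flatnonzero(F).tolist() == [21 * p for p in range(20)]


def test_flatten_bigram_reshape_inverse():
    rng = np.random.default_rng(10)
    B = rng.random((20, 20))
    F = flatten_bigram(pg.BigramMatrix(B=B, source_rows=41))
    np.testing.assert_array_equal(F.reshape(20, 20), B)


def test_flatten_structural_position_major():
    W = np.zeros((7, 8))
    W[0, 0] = 1.5
    W[1, 0] = 2.5
    out = flatten_structural(W)
    assert out[0] == 1.5
    assert out[8] == 2.5  # row 2's first property lands at index 8


def test_flatten_structural_round_trip():
    rng = np.random.default_rng(11)
    W = rng.random((7, 8))
    np.testing.assert_array_equal(flatten_structural(W).reshape(7, 8), W)


def test_flatten_structural_rejects_wrong_shape():
    with pytest.raises(ValueError, match="7x8"):
        flatten_structural(np.zeros((7, 7)))


def _segment(seed=0, pssm_window=None):
    rng = np.random.default_rng(seed)
    return pg.Segment(
        site=pg.SiteLabel("p", 30, 1),
        structural_window=rng.random((7, 8)),
        pssm_window=(
            pssm_window
            if pssm_window is not None
            else random_row_stochastic(rng)
        ),
        source_indices_structural=list(range(27, 34)),
        source_indices_pssm=list(range(10, 51)),
    )


def test_feature_vector_dimension_456():
    v = pg.build_feature_vector(_segment())
    assert v.shape == (456,)
    assert len(pg.feature_names()) == 456


def test_feature_vector_uniform_pssm_bigram_block():
    seg = _segment(pssm_window=np.full((41, 20), 0.05))
    v = pg.build_feature_vector(seg)
    np.testing.assert_allclose(v[56:], 0.1)


def test_feature_vector_deterministic():
    np.testing.assert_array_equal(
        pg.build_feature_vector(_segment(seed=3)),
        pg.build_feature_vector(_segment(seed=3)),
    )


def test_feature_vector_layout_matches_names():
    seg = _segment(seed=4)
    v = pg.build_feature_vector(seg)
    names = pg.feature_names()
    # structural block: position-major, offset -3 first
    assert names[0] == "struct_pos-3_asa"
    assert v[0] == seg.structural_window[0, 0]
    assert names[8] == "struct_pos-2_asa"
    assert v[8] == seg.structural_window[1, 0]
    assert names[56] == "bigram_A_A"
    assert names[-1] == "bigram_V_V"


def test_feature_invariant_to_content_outside_windows(tiny_dataset):
    """Editing profile rows beyond the +/-20 window leaves the vector
    unchanged."""
    ds = tiny_dataset
    site = next(
        s
        for s in ds.sites
        if 21 <= s.position <= ds.pssms[s.protein_id].length - 21
    )
    pssm = ds.pssms[site.protein_id]
    struct = ds.structs[site.protein_id]
    v1 = pg.build_feature_vector(pg.extract_segment(site, pssm, struct))
    edited = pssm.matrix.copy()
    far = site.position + 25
    if far <= pssm.length:
        edited[far - 1] = np.roll(edited[far - 1], 3)
    edited[: max(site.position - 21, 0)] = 0.05  # rows still sum to 1
    pssm2 = pg.PssmProfile(protein_id=pssm.protein_id, matrix=edited)
    v2 = pg.build_feature_vector(pg.extract_segment(site, pssm2, struct))
    np.testing.assert_array_equal(v1, v2)


def test_featurize_dataset_shapes_and_names(tiny_dataset, tiny_table):
    assert len(tiny_table) == len(tiny_dataset.sites)
    assert tiny_table.n_features == 456
    assert tiny_table.column_names == pg.feature_names()
    assert tiny_table.site_ids == [
        (s.protein_id, s.position) for s in tiny_dataset.sites
    ]


def test_featurize_dataset_missing_profile_listed(tiny_dataset):
    ds = tiny_dataset
    pssms = dict(ds.pssms)
    dropped = ds.sites[0].protein_id
    del pssms[dropped]
    with pytest.raises(ValueError, match=dropped):
        pg.featurize_dataset(ds.sites, pssms, ds.structs)
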