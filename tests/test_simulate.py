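import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from stormclust import (
    FieldGeometry,
    SyntheticConfig,
    generate_clustered_field,
    generate_monomer_field,
    generate_two_color_field,
    nearest_neighbor_distances,
)
from stormclust.errors import FeasibilityError, SizeError, ValidationError
from stormclust.simulate import _ztp_rate, sample_blink_counts


def test_config_mode_is_exclusive(square_10um):
    with pytest.raises(ValidationError):
        SyntheticConfig(geometry=square_10um)
    with pytest.raises(ValidationError):
        SyntheticConfig(geometry=square_10um, molecule_density=5, cluster_density=5)


def test_determinism_identical_seed_bit_identical(square_10um):
    cfg = SyntheticConfig(geometry=square_10um, molecule_density=3, seed=42)
    t1, tr1 = generate_monomer_field(cfg)
    t2, tr2 = generate_monomer_field(cfg)
    assert t1.data.equals(t2.data)
    assert tr1.molecules.equals(tr2.molecules)


def test_blink_conservation_and_truth_links(square_10um):
    cfg = SyntheticConfig(geometry=square_10um, molecule_density=10, seed=3)
    table, truth = generate_monomer_field(cfg)
    assert truth.molecules["blink_count"].sum() == len(table)
    assert len(truth.blink_molecule) == len(table)
    counts = np.bincount(truth.blink_molecule, minlength=len(truth.molecules))
    np.testing.assert_array_equal(counts, truth.molecules["blink_count"].to_numpy())


def test_molecule_count_matches_poisson_expectation(square_10um):
    # fixed_count pins the draw at the rounded expectation
    cfg = SyntheticConfig(geometry=square_10um, molecule_density=72, seed=0, fixed_count=True)
    _, truth = generate_monomer_field(cfg)
    assert len(truth.molecules) == 7200


@pytest.mark.parametrize("model", ["zero_truncated_poisson", "geometric"])
def test_blink_mean_law_of_large_numbers(model, rng):
    counts = sample_blink_counts(rng, 20_000, model, 6.6)
    assert counts.min() >= 1
    assert 6.5 <= counts.mean() <= 6.7


def test_ztp_rate_inverts_mean():
    for mean in (1.5, 3.0, 6.6, 20.0):
        lam = _ztp_rate(mean)
        assert lam / (1 - np.exp(-lam)) == pytest.approx(mean, rel=1e-9)


def test_zero_noise_fixed_single_blink_is_exact(square_10um):
    cfg = SyntheticConfig(
        geometry=square_10um, molecule_density=5, blink_model="fixed", blink_mean=1,
        loc_sigma=0.0, seed=5,
    )
    table, truth = generate_monomer_field(cfg)
    np.testing.assert_allclose(table.points(), truth.molecules[["true_x", "true_y"]].to_numpy())


def test_localization_spread_matches_loc_sigma(square_10um):
    # a handful of molecules with ~2000 blinks each
    cfg = SyntheticConfig(
        geometry=square_10um, molecule_density=0.1, blink_model="fixed",
        blink_mean=2000, loc_sigma=12.0, seed=8, fixed_count=True,
    )
    table, truth = generate_monomer_field(cfg)
    pts = table.points()
    for mol in truth.molecules["molecule_id"]:
        blinks = pts[truth.blink_molecule == mol]
        center = truth.molecules.loc[mol, ["true_x", "true_y"]].to_numpy(dtype=float)
        disp = blinks - center  # safe: molecules sit away from the wrap seam w.h.p.
        sd = np.sqrt((disp**2).mean())
        assert abs(sd - 12.0) / 12.0 < 0.05


def test_size_guard(square_10um):
    cfg = SyntheticConfig(geometry=square_10um, molecule_density=2e6, seed=0)
    with pytest.raises(SizeError):
        generate_monomer_field(cfg)


def test_clustered_field_counts_and_membership(square_10um):
    cfg = SyntheticConfig(
        geometry=square_10um, cluster_density=11, copies_per_cluster=7,
        domain_sigma=15.0, seed=1, fixed_count=True,
    )
    table, truth = generate_clustered_field(cfg)
    assert len(truth.domains) == 1100
    assert len(truth.molecules) == 7700
    sizes = truth.molecules.groupby("domain_id").size()
    assert (sizes == 7).all()


def test_degenerate_domain_collapses_to_loc_sigma(square_10um):
    cfg = SyntheticConfig(
        geometry=square_10um, cluster_density=0.5, copies_per_cluster=5,
        domain_sigma=0.0, blink_model="fixed", blink_mean=200, loc_sigma=10.0,
        seed=2, fixed_count=True,
    )
    table, truth = generate_clustered_field(cfg)
    pts = table.points()
    mol_dom = truth.molecules.set_index("molecule_id")["domain_id"]
    for dom, group in truth.molecules.groupby("domain_id"):
        xy = group[["true_x", "true_y"]].to_numpy()
        assert np.allclose(xy, xy[0])  # molecules coincide
        blinks = pts[np.isin(truth.blink_molecule, group["molecule_id"])]
        sd = np.sqrt(((blinks - xy[0]) ** 2).mean())
        assert abs(sd - 10.0) / 10.0 < 0.1


def test_single_copy_clusters_match_monomer_statistics():
    """copies_per_cluster=1 is CSR: NND statistics indistinguishable from monomer mode.

    NND values within one field are mutually dependent (mutual nearest
    neighbors duplicate distances), which makes the two-sample KS test
    anti-conservative: its measured null rejection rate at nominal
    alpha=0.01 is ~6-7% on monomer-vs-monomer fields. The allowance below
    is the 99.5% binomial bound at that measured null rate; the pooled
    mean-NND check against the CSR closed form 1/(2 sqrt(lambda)) is exact.
    """
    geom = FieldGeometry.square_um(5, "toroidal")
    rejections = 0
    pooled_mono, pooled_clus = [], []
    for seed in range(10):
        mono = SyntheticConfig(geometry=geom, molecule_density=20, seed=seed)
        clus = SyntheticConfig(geometry=geom, cluster_density=20, copies_per_cluster=1,
                               domain_sigma=0.0, seed=seed + 100)
        _, tm = generate_monomer_field(mono)
        _, tc = generate_clustered_field(clus)
        d1 = nearest_neighbor_distances(tm.molecules[["true_x", "true_y"]].to_numpy(), geom)
        d2 = nearest_neighbor_distances(tc.molecules[["true_x", "true_y"]].to_numpy(), geom)
        pooled_mono.append(d1)
        pooled_clus.append(d2)
        if ks_2samp(d1, d2).pvalue < 0.01:
            rejections += 1
    assert rejections <= 3
    expected = 1.0 / (2.0 * np.sqrt(20e-6))  # nm
    # per-field NND means fluctuate ~+/-2% (within-field dependence); 3% bounds both modes
    assert abs(np.concatenate(pooled_mono).mean() - expected) / expected < 0.03
    assert abs(np.concatenate(pooled_clus).mean() - expected) / expected < 0.03


def test_two_color_colocalized_sigma_zero_coincides(square_3um):
    cfg = SyntheticConfig(geometry=square_3um, molecule_density=30, seed=4)
    table, truth = generate_two_color_field(cfg, cfg, mode="colocalized",
                                            coupling_sigma=0.0, seed=9)
    mols = truth.molecules
    a = mols[mols.channel == 0][["true_x", "true_y"]].to_numpy()
    b = mols[mols.channel == 1][["true_x", "true_y"]].to_numpy()
    d, _ = cKDTree(a).query(b)
    assert d.max() == 0.0


def test_two_color_excluded_respects_hardcore(square_3um):
    cfg = SyntheticConfig(geometry=square_3um, molecule_density=20, seed=4)
    table, truth = generate_two_color_field(cfg, cfg, mode="excluded",
                                            hardcore_radius=200.0, seed=10)
    mols = truth.molecules
    a = mols[mols.channel == 0][["true_x", "true_y"]].to_numpy()
    b = mols[mols.channel == 1][["true_x", "true_y"]].to_numpy()
    box = (square_3um.width, square_3um.height)
    d, _ = cKDTree(np.mod(a, box), boxsize=box).query(np.mod(b, box))
    assert d.min() >= 200.0


def test_two_color_excluded_infeasible_raises(square_3um):
    cfg = SyntheticConfig(geometry=square_3um, molecule_density=50, seed=4)
    with pytest.raises(FeasibilityError):
        generate_two_color_field(cfg, cfg, mode="excluded", hardcore_radius=2500.0, seed=1)


def test_two_color_channels_are_contiguous(square_3um):
    cfg = SyntheticConfig(geometry=square_3um, molecule_density=10, seed=0)
    table, truth = generate_two_color_field(cfg, cfg, mode="independent", seed=2)
    assert table.n_channels == 2
    assert truth.molecules["blink_count"].sum() == len(table)
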