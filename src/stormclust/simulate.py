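"""Ground-truthed synthetic STORM localization fields.

Emulates fields of membrane-protein molecules imaged by single-molecule
localization microscopy: molecules are placed by a homogeneous Poisson
process (monomer mode) or grouped into multi-molecule nanodomains
(clustered mode); each labeled molecule emits a random number of blinks
whose positions are the true position plus isotropic Gaussian localization
error. Two-color fields support independent, co-localized and excluded
inter-channel structure.

Blink-count distributions: repeated photoswitching of one dye-tagged
antibody yields on average ~6.6 detected blinks, but the full distribution
is not constrained by the downstream analysis (only the mean enters the
copy-number ratio), so the family is configurable: ``fixed``,
``zero_truncated_poisson`` (default; every labeled molecule appears at
least once) or ``geometric``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import FeasibilityError, ParameterError, SizeError, ValidationError
from .geometry import FieldGeometry
from .loc_io import LocalizationTable

_MAX_MOLECULES = 10_000_000
_MAX_REJECTIONS = 10_000

BLINK_MODELS = ("fixed", "zero_truncated_poisson", "geometric")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic channel.

    Exactly one of ``molecule_density`` (monomer mode, molecules per um^2)
    or ``cluster_density`` (clustered mode, nanodomains per um^2, with
    ``copies_per_cluster`` molecules spread by ``domain_sigma`` nm about
    each domain center) must be set. ``loc_sigma`` is the per-axis SD of
    the isotropic Gaussian localization error in nm; antibody-linkage
    displacement is absorbed into it rather than modeled separately.
    ``fixed_count`` replaces the Poisson molecule/domain number by its
    rounded expectation for exact-count tests.
    """

    geometry: FieldGeometry
    molecule_density: Optional[float] = None
    cluster_density: Optional[float] = None
    copies_per_cluster: int = 1
    domain_sigma: float = 0.0
    blink_mean: float = 6.6
    blink_model: str = "zero_truncated_poisson"
    loc_sigma: float = 10.0
    seed: int = 0
    fixed_count: bool = False

    def __post_init__(self) -> None:
        if (self.molecule_density is None) == (self.cluster_density is None):
            raise ValidationError(
                "set exactly one of molecule_density (monomer) or cluster_density (clustered)"
            )
        density = self.molecule_density if self.molecule_density is not None else self.cluster_density
        if density < 0:
            raise ValidationError("density must be >= 0")
        if self.cluster_density is not None and self.copies_per_cluster < 1:
            raise ParameterError("copies_per_cluster must be >= 1")
        if self.blink_mean < 1:
            raise ValidationError("blink_mean must be >= 1")
        if self.blink_model not in BLINK_MODELS:
            raise ValidationError(f"unknown blink_model {self.blink_model!r}")
        if self.loc_sigma < 0 or self.domain_sigma < 0:
            raise ValidationError("sigmas must be >= 0")

    @property
    def is_clustered(self) -> bool:
        return self.cluster_density is not None


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic field.

    ``molecules`` has one row per molecule (molecule_id, channel, domain_id,
    true_x, true_y, blink_count); ``domains`` one row per nanodomain center;
    ``blink_molecule`` maps each row of the emitted table to its molecule_id.
    """

    molecules: pd.DataFrame
    domains: pd.DataFrame
    blink_molecule: np.ndarray

    def validate(self, table: LocalizationTable) -> None:
        if int(self.molecules["blink_count"].sum()) != len(table):
            raise ValidationError("blink counts do not sum to the table size")
        if not np.isin(self.blink_molecule, self.molecules["molecule_id"].to_numpy()).all():
            raise ValidationError("blink references an unknown molecule")


def _ztp_rate(mean: float) -> float:
    """Rate lambda of a zero-truncated Poisson with the given mean."""
    if mean <= 1.0 + 1e-12:
        return 0.0
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return brentq(f, 1e-10, mean)


def sample_blink_counts(rng: np.random.Generator, n: int, model: str, mean: float) -> np.ndarray:
    """Draw per-molecule blink counts (support {1, 2, ...}, expectation ~ mean)."""
    if model == "fixed":
        k = int(round(mean))
        return np.full(n, max(k, 1), dtype=np.int64)
    if model == "zero_truncated_poisson":
        lam = _ztp_rate(mean)
        if lam == 0.0:
            return np.ones(n, dtype=np.int64)
        out = rng.poisson(lam, size=n)
        while True:
            zero = out == 0
            if not zero.any():
                return out.astype(np.int64)
            out[zero] = rng.poisson(lam, size=int(zero.sum()))
    if model == "geometric":
        return rng.geometric(1.0 / mean, size=n).astype(np.int64)
    raise ParameterError(f"unknown blink_model {model!r}")


def _draw_count(rng: np.random.Generator, density: float, area_um2: float, fixed: bool) -> int:
    mean = density * area_um2
    if mean > _MAX_MOLECULES:
        raise SizeError(f"requested ~{mean:.3g} molecules; refusing fields beyond {_MAX_MOLECULES:.0g}")
    return int(round(mean)) if fixed else int(rng.poisson(mean))


def _emit_blinks(
    rng: np.random.Generator,
    molecules_xy: np.ndarray,
    blink_counts: np.ndarray,
    loc_sigma: float,
    geometry: FieldGeometry,
) -> Tuple[np.ndarray, np.ndarray]:
    """Blink positions (true position + Gaussian error) and blink->molecule map."""
    total = int(blink_counts.sum())
    parent = np.repeat(np.arange(len(molecules_xy)), blink_counts)
    xy = molecules_xy[parent] + rng.normal(0.0, loc_sigma, size=(total, 2))
    if geometry.is_toroidal:
        xy = geometry.wrap(xy)
    else:
        # open boundary: redraw the displacement until the blink lands inside
        bad = ~geometry.contains(xy)
        while bad.any():
            idx = np.flatnonzero(bad)
            xy[idx] = molecules_xy[parent[idx]] + rng.normal(0.0, loc_sigma, size=(len(idx), 2))
            bad = ~geometry.contains(xy)
    return xy, parent


def _assemble(
    rng: np.random.Generator,
    geometry: FieldGeometry,
    molecules_xy: np.ndarray,
    domain_id: np.ndarray,
    domains_xy: np.ndarray,
    blink_counts: np.ndarray,
    loc_sigma: float,
    channel: int = 0,
) -> Tuple[LocalizationTable, SyntheticTruth]:
    xy, parent = _emit_blinks(rng, molecules_xy, blink_counts, loc_sigma, geometry)
    n_mol = len(molecules_xy)
    frames = rng.integers(0, 20_000, size=len(xy))
    table = LocalizationTable.from_arrays(
        xy[:, 0], xy[:, 1], frame=frames,
        channel=np.full(len(xy), channel, dtype=np.int64),
        geometry=geometry,
    )
    molecules = pd.DataFrame(
        {
            "molecule_id": np.arange(n_mol, dtype=np.int64),
            "channel": np.full(n_mol, channel, dtype=np.int64),
            "domain_id": domain_id.astype(np.int64),
            "true_x": molecules_xy[:, 0],
            "true_y": molecules_xy[:, 1],
            "blink_count": blink_counts.astype(np.int64),
        }
    )
    domains = pd.DataFrame(
        {
            "domain_id": np.arange(len(domains_xy), dtype=np.int64),
            "channel": np.full(len(domains_xy), channel, dtype=np.int64),
            "center_x": domains_xy[:, 0] if len(domains_xy) else np.array([]),
            "center_y": domains_xy[:, 1] if len(domains_xy) else np.array([]),
        }
    )
    truth = SyntheticTruth(molecules, domains, parent)
    truth.validate(table)
    return table, truth


def _place_molecules(
    rng: np.random.Generator, config: SyntheticConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Molecule positions, their domain ids, and domain centers."""
    g = config.geometry
    if not config.is_clustered:
        n = _draw_count(rng, config.molecule_density, g.area_um2, config.fixed_count)
        xy = rng.uniform([0, 0], [g.width, g.height], size=(n, 2))
        return xy, np.full(n, -1, dtype=np.int64), np.empty((0, 2))
    n_dom = _draw_count(rng, config.cluster_density, g.area_um2, config.fixed_count)
    centers = rng.uniform([0, 0], [g.width, g.height], size=(n_dom, 2))
    copies = config.copies_per_cluster
    domain_id = np.repeat(np.arange(n_dom), copies)
    xy = centers[domain_id] + rng.normal(0.0, config.domain_sigma, size=(n_dom * copies, 2))
    if g.is_toroidal:
        xy = g.wrap(xy)
    else:
        bad = ~g.contains(xy)
        while bad.any():
            idx = np.flatnonzero(bad)
            xy[idx] = centers[domain_id[idx]] + rng.normal(0.0, config.domain_sigma, size=(len(idx), 2))
            bad = ~g.contains(xy)
    return xy, domain_id, centers


def generate_monomer_field(config: SyntheticConfig) -> Tuple[LocalizationTable, SyntheticTruth]:
    """Homogeneous Poisson field of monomeric molecules."""
    if config.is_clustered:
        raise ParameterError("generate_monomer_field requires a monomer-mode config")
    rng = np.random.default_rng(config.seed)
    xy, domain_id, centers = _place_molecules(rng, config)
    counts = sample_blink_counts(rng, len(xy), config.blink_model, config.blink_mean)
    return _assemble(rng, config.geometry, xy, domain_id, centers, counts, config.loc_sigma)


def generate_clustered_field(config: SyntheticConfig) -> Tuple[LocalizationTable, SyntheticTruth]:
    """Poisson-placed nanodomains, each holding exactly ``copies_per_cluster`` molecules."""
    if not config.is_clustered:
        raise ParameterError("generate_clustered_field requires a clustered-mode config")
    rng = np.random.default_rng(config.seed)
    xy, domain_id, centers = _place_molecules(rng, config)
    counts = sample_blink_counts(rng, len(xy), config.blink_model, config.blink_mean)
    return _assemble(rng, config.geometry, xy, domain_id, centers, counts, config.loc_sigma)


def generate_field(config: SyntheticConfig) -> Tuple[LocalizationTable, SyntheticTruth]:
    """Dispatch on the config's mode."""
    if config.is_clustered:
        return generate_clustered_field(config)
    return generate_monomer_field(config)


TWO_COLOR_MODES = ("independent", "colocalized", "excluded")


def generate_two_color_field(
    config_a: SyntheticConfig,
    config_b: SyntheticConfig,
    mode: str = "independent",
    coupling_sigma: float = 0.0,
    hardcore_radius: float = 0.0,
    seed: int = 0,
) -> Tuple[LocalizationTable, SyntheticTruth]:
    """Two-channel field with configurable inter-channel structure.

    ``independent`` draws the channels independently; ``colocalized`` places
    channel-1 molecules at channel-0 molecule positions plus an isotropic
    Gaussian of SD ``coupling_sigma``; ``excluded`` redraws channel-1
    molecules until each lies at least ``hardcore_radius`` from every
    channel-0 molecule.
    """
    if mode not in TWO_COLOR_MODES:
        raise ParameterError(f"unknown two-color mode {mode!r}")
    if config_a.geometry != config_b.geometry:
        raise ParameterError("both channels must share the field geometry")
    g = config_a.geometry
    rng = np.random.default_rng(seed)
    seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)

    rng_a = np.random.default_rng(seed_a)
    xy_a, dom_a, centers_a = _place_molecules(rng_a, config_a)
    counts_a = sample_blink_counts(rng_a, len(xy_a), config_a.blink_model, config_a.blink_mean)
    table_a, truth_a = _assemble(rng_a, g, xy_a, dom_a, centers_a, counts_a, config_a.loc_sigma)

    rng_b = np.random.default_rng(seed_b)
    if mode == "independent":
        xy_b, dom_b, centers_b = _place_molecules(rng_b, config_b)
    elif mode == "colocalized":
        if len(xy_a) == 0:
            raise FeasibilityError("colocalized mode requires a nonempty channel 0")
        density_b = config_b.molecule_density if not config_b.is_clustered else (
            config_b.cluster_density * config_b.copies_per_cluster
        )
        n_b = _draw_count(rng_b, density_b, g.area_um2, config_b.fixed_count)
        parents = rng_b.permutation(len(xy_a))[:n_b] if n_b <= len(xy_a) else rng_b.integers(0, len(xy_a), n_b)
        xy_b = xy_a[parents] + rng_b.normal(0.0, coupling_sigma, size=(n_b, 2))
        xy_b = g.wrap(xy_b) if g.is_toroidal else np.clip(xy_b, 0, [g.width, g.height])
        dom_b, centers_b = np.full(n_b, -1, dtype=np.int64), np.empty((0, 2))
    else:  # excluded
        xy_b, dom_b, centers_b = _place_molecules(rng_b, config_b)
        if len(xy_a) and len(xy_b):
            boxsize = (g.width, g.height) if g.is_toroidal else None
            tree = cKDTree(xy_a, boxsize=boxsize)
            for i in range(len(xy_b)):
                tries = 0
                while tree.query(xy_b[i])[0] < hardcore_radius:
                    tries += 1
                    if tries > _MAX_REJECTIONS:
                        raise FeasibilityError(
                            f"hard-core radius {hardcore_radius} nm infeasible at this density"
                        )
                    xy_b[i] = rng_b.uniform([0, 0], [g.width, g.height])
    counts_b = sample_blink_counts(rng_b, len(xy_b), config_b.blink_model, config_b.blink_mean)
    table_b, truth_b = _assemble(rng_b, g, xy_b, dom_b, centers_b, counts_b, config_b.loc_sigma)

    # merge the channels, offsetting channel-1 ids past channel-0's
    off_mol = len(truth_a.molecules)
    off_dom = len(truth_a.domains)
    df_b = table_b.data.copy()
    df_b["blink_id"] += len(table_a)
    df_b["channel"] = 1
    data = pd.concat([table_a.data, df_b], ignore_index=True)
    table = LocalizationTable(data, g)
    mol_b = truth_b.molecules.copy()
    mol_b["molecule_id"] += off_mol
    mol_b["channel"] = 1
    mol_b.loc[mol_b["domain_id"] >= 0, "domain_id"] += off_dom
    dom_b2 = truth_b.domains.copy()
    dom_b2["domain_id"] += off_dom
    dom_b2["channel"] = 1
    truth = SyntheticTruth(
        pd.concat([truth_a.molecules, mol_b], ignore_index=True),
        pd.concat([truth_a.domains, dom_b2], ignore_index=True),
        np.concatenate([truth_a.blink_molecule, truth_b.blink_molecule + off_mol]),
    )
    truth.validate(table)
    return table, truth
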