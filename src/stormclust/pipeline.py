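"""End-to-end orchestration: simulate -> cluster -> metrics -> spatial/xcorr.

A :class:`RunConfig` collects every tunable that affects numbers; reports
echo the full configuration with a content hash and seed, so a seeded run
is exactly reproducible. Per-field (per-cell) summaries are the unit of
statistical comparison between conditions, tested with an unpaired
two-sample t-test (classic equal-variance form by default, Welch optional).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import yaml
from scipy import stats as sps

from . import __version__
from .clustering import ClusterAssignment, ClusterParams, developed_dbscan
from .errors import ParameterError, UndefinedStatisticError, ValidationError
from .geometry import FieldGeometry
from .loc_io import (
    LocalizationTable,
    read_cluster_table,
    read_localizations,
    write_cluster_table,
    write_localizations,
)
from .metrics import FieldSummary, summarize_field
from .simulate import SyntheticConfig, generate_field

log = logging.getLogger("stormclust")

SIGNIFICANCE_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for cut, tier in SIGNIFICANCE_TIERS:
        if p < cut:
            return tier
    return "ns"


@dataclass
class RunConfig:
    """Configuration of one field analysis.

    Exactly one input source: ``simulate`` (SyntheticConfig parameters as a
    mapping) or ``localizations`` (path). Clustering runs with ``cluster``
    parameters unless a precomputed ``cluster_table`` path is given.
    """

    outdir: Optional[str] = None
    seed: int = 0
    simulate: Optional[Dict[str, Any]] = None
    localizations: Optional[str] = None
    dialect: str = "native"
    cluster: Dict[str, Any] = field(default_factory=dict)
    cluster_table: Optional[str] = None
    background_blinks: Optional[float] = None
    surface_area_um2: float = 150.0
    min_overlay_blinks: int = 3

    def validate(self) -> None:
        if (self.simulate is None) == (self.localizations is None):
            raise ValidationError("provide exactly one of 'simulate' or 'localizations'")
        if self.localizations is not None and not Path(self.localizations).exists():
            raise ValidationError(f"input file {self.localizations!r} does not exist")
        if self.cluster_table is not None and not Path(self.cluster_table).exists():
            raise ValidationError(f"cluster table {self.cluster_table!r} does not exist")
        self.cluster_params()  # raises on invalid parameters
        if self.simulate is not None:
            self.synthetic_config()

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(**self.cluster)

    def synthetic_config(self) -> SyntheticConfig:
        spec = dict(self.simulate or {})
        geom = spec.pop("geometry", {"width": 10_000.0, "height": 10_000.0, "boundary": "toroidal"})
        if isinstance(geom, dict):
            geom = FieldGeometry(**geom)
        spec.setdefault("seed", self.seed)
        return SyntheticConfig(geometry=geom, **spec)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        return cls(**data)


def config_hash(config: Dict[str, Any]) -> str:
    """Hash of every tunable that affects numbers (output locations excluded)."""
    pruned = {k: v for k, v in config.items() if k != "outdir"}
    blob = json.dumps(pruned, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _assignment_from_table(df, table: LocalizationTable) -> ClusterAssignment:
    order = df.set_index("blink_id")
    ids = table.data["blink_id"].to_numpy()
    coarse = order.loc[ids, "coarse_label"].to_numpy()
    final = order.loc[ids, "final_label"].to_numpy()
    return ClusterAssignment(table, coarse, final)


def run_field_analysis(config: RunConfig) -> FieldSummary:
    """Execute the configured stages; write artifacts if an outdir is set."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        syn = config.synthetic_config()
        log.info("simulating field: %s", syn)
        table, truth = generate_field(syn)
        if outdir:
            write_localizations(table, outdir / "localizations.csv")
            truth.molecules.to_csv(outdir / "truth_molecules.csv", index=False)
    else:
        table = read_localizations(config.localizations, dialect=config.dialect)
    log.info("field: %d localizations over %.1f um^2", len(table), table.geometry.area_um2)
    params = config.cluster_params()
    if config.cluster_table is not None:
        assignment = _assignment_from_table(read_cluster_table(config.cluster_table), table)
    else:
        assignment = developed_dbscan(table, params)
        if outdir:
            write_cluster_table(assignment, outdir / "clusters.csv")
    log.info(
        "clusters: %d coarse -> %d final (%d noise blinks)",
        assignment.n_coarse_clusters,
        assignment.n_final_clusters,
        int(np.sum(assignment.final_label == -1)),
    )
    echo = config.to_dict()
    echo["cluster"] = dataclasses.asdict(params)
    summary = summarize_field(
        assignment,
        background_blinks=config.background_blinks,
        min_overlay_blinks=config.min_overlay_blinks,
        params=echo,
    )
    if outdir:
        write_report(summary, outdir / "summary.json")
    return summary


@dataclass
class ConditionComparison:
    """Unpaired two-sample comparison of one per-field metric."""

    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    difference: float
    t_statistic: float
    p_value: float
    tier: str
    equal_var: bool

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def compare_conditions(
    group_a: List[FieldSummary],
    group_b: List[FieldSummary],
    metric: str = "cluster_density",
    equal_var: bool = True,
) -> ConditionComparison:
    """Unpaired Student's t-test (Welch with ``equal_var=False``) on a per-field metric."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise UndefinedStatisticError("each group needs at least 2 field summaries")

    def extract(group: List[FieldSummary]) -> np.ndarray:
        vals = []
        for s in group:
            v = getattr(s, metric, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ParameterError(f"metric {metric!r} missing from a summary")
            vals.append(float(v))
        return np.array(vals)

    a, b = extract(group_a), extract(group_b)
    t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # both groups constant with equal means: no evidence of difference
        t_stat, p = 0.0, 1.0
    return ConditionComparison(
        metric=metric,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(b.mean() - a.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        tier=significance_tier(float(p)),
        equal_var=equal_var,
    )


def write_report(obj: FieldSummary | ConditionComparison, path: str | Path) -> None:
    """JSON report with provenance, plus a human-readable .txt alongside."""
    path = Path(path)
    payload = obj.to_dict()
    doc = {
        "stormclust_version": __version__,
        "config_hash": config_hash(payload.get("params") or payload),
        "report": payload,
    }
    path.write_text(json.dumps(doc, indent=2, default=_json_default) + "\n")
    lines = [f"stormclust {__version__} report ({doc['config_hash']})"]
    for key, val in payload.items():
        if key == "params":
            continue
        lines.append(f"  {key}: {val}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
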