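"""End-to-end orchestration: flow CSV -> per-period TSPs, calls, and tables.

A run is fully determined by (input, config, seed): every stage's output is
written as tidy CSV/JSON together with a manifest (config hash, seed, library
versions), so a run can be reproduced bit for bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flow_network import (
    ComponentReport,
    DyadStats,
    FlowTable,
    aggregate_periods,
    apply_flow_threshold,
    build_graph,
    component_report,
    dyad_decomposition,
    low_order_summary,
    read_flow_table,
    volume_vs_edges,
)
from .null_ensemble import RewireConfig
from .triads import TriadCensus, census
from .tsp import (
    SuperfamilyCall,
    TSProfile,
    classify_superfamily,
    compute_tsp,
    exemplar_triads,
    profile_table,
)

__all__ = ["PipelineConfig", "PeriodResult", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of a full analysis run.

    Defaults are the standard analysis settings: 100 people/year threshold
    (hence a 500-per-period cutoff on 5-year bins), a 200-member rewired
    ensemble, and automatic largest-component extraction for fragmented
    periods.
    """

    input: str | None = None
    columns: dict = field(default_factory=dict)
    span_years: int = 1  # aggregate annual input into bins of this width
    threshold_per_year: float = 100.0
    largest_component: str = "auto"  # auto | always | never
    ensemble_size: int = 200
    attempts_per_arc: float = 100.0
    seed: int = 0
    z_min: float = 0.05
    exemplar_min_z: float = 0.1
    exemplar_top_k: int = 1
    sigma_zero_cap: float = 10.0
    window_start: int = 1990
    reference_profiles: dict = field(default_factory=dict)
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise KeyError(f"unknown config keys: {sorted(bad)}")
        return cls(**payload)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Config without the output location (which does not affect results)."""
        d = self.as_dict()
        d.pop("outdir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PeriodResult:
    """All analysis products of one period."""

    period: object
    empty: bool = False
    dyads: DyadStats | None = None
    components: ComponentReport | None = None
    summary: dict | None = None
    census: TriadCensus | None = None
    profile: TSProfile | None = None
    superfamily: SuperfamilyCall | None = None
    exemplars: dict | None = None
    used_largest_component: bool = False


@dataclass
class PipelineResult:
    periods: dict
    volume_table: pd.DataFrame
    manifest: dict

    @property
    def profiles(self) -> list:
        return [r.profile for r in self.periods.values() if r.profile is not None]


def _period_seed(seed: int, period) -> int:
    """Deterministic per-period rewiring seed, kept below 2**31."""
    return int(np.random.SeedSequence([seed, int(period)]).generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig, table: FlowTable | None = None) -> PipelineResult:
    """Execute the full analysis, optionally writing the result bundle.

    Either ``cfg.input`` (a flow CSV) or an in-memory ``table`` must be
    supplied.  Stages per period: threshold -> dyad decomposition ->
    component report -> (largest component when fragmented) -> triad census
    -> rewired ensemble -> significance profile -> superfamily call ->
    exemplar triads.  Periods whose thresholded graph is empty are reported
    as such; the run continues.
    """
    if table is None:
        if cfg.input is None:
            raise ValueError("config needs an input path (or pass a table)")
        table = read_flow_table(cfg.input, dialect=cfg.columns or None)
    if cfg.span_years > 1 and table.span == 1:
        table = aggregate_periods(table, cfg.span_years, window_start=cfg.window_start)
    vol = volume_vs_edges(table, cfg.threshold_per_year)
    thresholded = apply_flow_threshold(table, cfg.threshold_per_year)
    results: dict = {}
    for period in table.periods:
        if period not in set(thresholded.periods):
            logger.warning("period %s: empty after thresholding", period)
            results[period] = PeriodResult(period, empty=True)
            continue
        g = build_graph(thresholded, period, keep_weights=True)
        res = PeriodResult(period)
        res.dyads = dyad_decomposition(g) if g.number_of_nodes() >= 2 else None
        res.components = component_report(g)
        res.summary = low_order_summary(g)
        fragmented = res.components.n_components > 1
        use_largest = cfg.largest_component == "always" or (
            cfg.largest_component == "auto" and fragmented
        )
        analysis = res.components.largest_component if use_largest else g
        res.used_largest_component = use_largest
        res.census = census(analysis)
        rewire_cfg = RewireConfig(
            attempts_per_arc=cfg.attempts_per_arc,
            ensemble_size=cfg.ensemble_size,
            seed=_period_seed(cfg.seed, period),
        )
        res.profile = compute_tsp(
            analysis, rewire_cfg, period=period, cap=cfg.sigma_zero_cap
        )
        res.superfamily = classify_superfamily(
            res.profile, refs=cfg.reference_profiles or None, z_min=cfg.z_min
        )
        over = [i + 1 for i in range(13) if res.profile.z[i] >= cfg.exemplar_min_z]
        res.exemplars = (
            exemplar_triads(analysis, over, top_k=cfg.exemplar_top_k) if over else {}
        )
        results[period] = res
    manifest = {
        "config": cfg.analysis_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": _versions(),
        "n_periods": len(results),
    }
    out = PipelineResult(results, vol, manifest)
    if cfg.outdir:
        write_bundle(out, Path(cfg.outdir))
    return out


def _versions() -> dict:
    import networkx
    import numba

    return {
        "triadflow": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "numba": numba.__version__,
    }


# ---------------------------------------------------------------------------
# result bundle serialization
# ---------------------------------------------------------------------------

def _dyad_rows(results) -> pd.DataFrame:
    rows = []
    for period, r in results.items():
        if r.empty or r.dyads is None:
            continue
        d = r.dyads
        rows.append(
            {
                "period": period,
                "n_nodes": d.n_nodes,
                "n_mutual": d.n_mutual,
                "n_asym": d.n_asym,
                "m": d.m,
                "a": d.a,
                "overall": d.overall,
            }
        )
    return pd.DataFrame(rows)


def _component_rows(results) -> pd.DataFrame:
    rows = []
    for period, r in results.items():
        if r.empty:
            continue
        c = r.components
        rows.append(
            {
                "period": period,
                "n_components": c.n_components,
                "largest_size": c.component_sizes[0],
                "flow_fraction_largest": c.flow_fraction_largest,
                "flow_fraction_second": c.flow_fraction_second,
            }
        )
    return pd.DataFrame(rows)


def _census_rows(results) -> pd.DataFrame:
    rows = []
    for period, r in results.items():
        if r.empty:
            continue
        row = {"period": period, **r.census.as_dict()}
        row["n_connected_triples"] = r.census.n_connected_triples
        rows.append(row)
    return pd.DataFrame(rows)


def _tsp_rows(results) -> pd.DataFrame:
    rows = []
    for period, r in results.items():
        if r.empty or r.profile is None:
            continue
        row = {"period": period}
        for i in range(13):
            row[f"z{i + 1}"] = float(r.profile.z[i])
        row["flags"] = ";".join(
            f"t{i + 1}:{'|'.join(sorted(f))}" for i, f in enumerate(r.profile.flags) if f
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _exemplar_rows(results) -> pd.DataFrame:
    rows = []
    for period, r in results.items():
        if r.empty or not r.exemplars:
            continue
        for cls in sorted(r.exemplars):
            for ex in r.exemplars[cls]:
                rows.append(
                    {
                        "period": period,
                        "triad_type": cls,
                        "nodes": "|".join(map(str, ex.nodes)),
                        "roles": "|".join(ex.roles),
                        "volume": ex.volume,
                    }
                )
    return pd.DataFrame(rows)


def write_bundle(result: PipelineResult, outdir: Path) -> None:
    """Write every stage's table plus the run manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.volume_table.to_csv(outdir / "volume_vs_edges.csv", index=False)
    _dyad_rows(result.periods).to_csv(outdir / "dyads.csv", index=False)
    _component_rows(result.periods).to_csv(outdir / "components.csv", index=False)
    _census_rows(result.periods).to_csv(outdir / "census.csv", index=False)
    _tsp_rows(result.periods).to_csv(outdir / "tsp.csv", index=False)
    _exemplar_rows(result.periods).to_csv(outdir / "exemplars.csv", index=False)
    profiles = result.profiles
    if profiles:
        profile_table(profiles).to_csv(outdir / "tsp_long.csv", index=False)
    calls = {
        str(period): {
            "label": r.superfamily.label,
            "evidence": r.superfamily.evidence,
            "correlation": r.superfamily.correlation,
        }
        for period, r in result.periods.items()
        if not r.empty and r.superfamily is not None
    }
    (outdir / "superfamily.json").write_text(json.dumps(calls, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )
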