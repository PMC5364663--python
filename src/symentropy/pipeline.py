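"""Orchestration of the two analyses:

* **group sweep** — NCSE of every segment in each condition group across a
  threshold-offset grid, summarized as a per-group mean ± SD table (plus the
  offset maximizing each group's mean);
* **electrode comparison** — per-electrode, per-threshold rank tests of
  per-subject NCSE between an eyes-closed and an eyes-open recording set,
  side by side with the same comparison on per-subject multiscale-entropy
  curves over a scale grid; summarized as max medians, minimum p and its
  setting, significance tier, and the contiguous significant setting ranges.

Both runs are deterministic given (config, seed) and write TSV tables (2
decimals for display, full precision in a ``*_full.tsv`` sidecar) plus a
JSON run manifest recording the configuration and its hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .io import Montage, Recording, Segment, load_montage, write_table
from .multiscale import MSEParams, mse_curve
from .stats import (
    GroupComparison,
    best_setting,
    mww_test,
    paired_test,
    significant_ranges,
)
from .symbolic import SymbolizationParams, ncse, ncse_sweep

__all__ = ["RunConfig", "Table1Result", "Table2Result",
           "run_group_sweep", "run_electrode_comparison", "export_topomap_table"]

log = logging.getLogger("symentropy")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, in one reproducible record."""

    psi: int = 2
    word_length: int = 3
    rule: str = "ge_mean_plus_xi"
    convention: str = "cardinality"
    xis: Sequence[float] = tuple(float(x) for x in range(15, 51, 5))
    mse_m: int = 1
    mse_r_frac: float = 0.25
    mse_scales: Sequence[int] = tuple(range(1, 21))
    include_mse: bool = True
    paired: bool = False
    out_dir: Optional[Path] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "xis", tuple(float(x) for x in self.xis))
        object.__setattr__(self, "mse_scales", tuple(int(s) for s in self.mse_scales))
        if self.out_dir is not None:
            object.__setattr__(self, "out_dir", Path(self.out_dir))

    def symbolization(self, xi: float = 0.0) -> SymbolizationParams:
        return SymbolizationParams(psi=self.psi, xi=xi, rule=self.rule)  # type: ignore[arg-type]

    def mse_params(self) -> MSEParams:
        return MSEParams(m=self.mse_m, r_frac=self.mse_r_frac, scales=self.mse_scales)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir) if self.out_dir else None
        d["xis"] = list(self.xis)
        d["mse_scales"] = list(self.mse_scales)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class Table1Result:
    """Per-group mean ± SD of NCSE across segments for each threshold offset."""

    table: pd.DataFrame  # columns: group, xi, mean, sd, n
    argmax_xi: dict[str, float]  # offset of the per-group mean-NCSE maximum
    config: RunConfig

    def matrix(self, stat: str = "mean") -> pd.DataFrame:
        return self.table.pivot(index="xi", columns="group", values=stat)


@dataclass(frozen=True)
class Table2Result:
    """Per-electrode NCSE-vs-MSE discrimination summary."""

    table: pd.DataFrame
    ncse_comparisons: dict[str, list[GroupComparison]]
    mse_comparisons: dict[str, list[GroupComparison]]
    config: RunConfig


def _write_manifest(config: RunConfig, out_dir: Path, extra: Mapping = ()) -> None:
    manifest = {"package": "symentropy", "version": _version,
                "config": config.to_dict(), "config_hash": config.config_hash()}
    manifest.update(dict(extra))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _write_display_and_sidecar(df: pd.DataFrame, out_dir: Path, stem: str) -> None:
    write_table(df, out_dir / f"{stem}.tsv", float_format="%.2f")
    write_table(df, out_dir / f"{stem}_full.tsv", float_format="%.10g")


def run_group_sweep(
    groups: Mapping[str, Sequence[Union[Segment, np.ndarray]]],
    config: RunConfig = RunConfig(),
) -> Table1Result:
    """NCSE threshold sweep per condition group (the five-set analysis).

    For every group, every segment's NCSE is evaluated at every offset of
    ``config.xis``; the group's mean ± SD per offset forms the result table.
    """
    if not groups:
        raise ValueError("need at least one group")
    log.info("group sweep: %d groups, grid %s, L=%d, psi=%d, rule=%s, convention=%s",
             len(groups), list(config.xis), config.word_length, config.psi,
             config.rule, config.convention)
    rows = []
    argmax: dict[str, float] = {}
    for name, segments in groups.items():
        segments = list(segments)
        if not segments:
            raise ValueError(f"group {name!r} has no segments")
        profile = ncse_sweep(segments, config.xis, config.symbolization(),
                             L=config.word_length, convention=config.convention)  # type: ignore[arg-type]
        for xi, m, s in zip(profile.xis, profile.mean, profile.sd):
            rows.append({"group": name, "xi": float(xi), "mean": float(m),
                         "sd": float(s), "n": len(segments)})
        argmax[name] = float(profile.xis[int(np.argmax(profile.mean))])
    table = pd.DataFrame(rows)
    result = Table1Result(table=table, argmax_xi=argmax, config=config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_display_and_sidecar(table, out, "group_sweep")
        _write_manifest(config, out, {"analysis": "group_sweep",
                                      "argmax_xi": argmax})
    return result


def _per_subject_ncse(recordings: Sequence[Recording], electrode: str,
                      xi: float, config: RunConfig) -> list[float]:
    params = config.symbolization(xi)
    return [ncse(rec.channels[electrode], params, L=config.word_length,
                 convention=config.convention).ncse  # type: ignore[arg-type]
            for rec in recordings]


def run_electrode_comparison(
    ec: Sequence[Recording],
    eo: Sequence[Recording],
    config: RunConfig = RunConfig(),
) -> Table2Result:
    """Per-electrode EC-vs-EO discrimination by NCSE (threshold grid) and,
    optionally, by MSE (scale grid).

    Per-subject metric values feed a two-sided rank test at each grid
    setting (unpaired MWW by default; Wilcoxon signed-rank when
    ``config.paired``).  Per electrode the table reports each condition's
    maximum median over the grid, the minimum p with its setting and tier,
    and the contiguous significant setting ranges.
    """
    ec, eo = list(ec), list(eo)
    if not ec or not eo:
        raise ValueError("need at least one recording per condition")
    electrodes_ec = set(ec[0].electrodes)
    electrodes_eo = set(eo[0].electrodes)
    only = electrodes_ec.symmetric_difference(electrodes_eo)
    if only:
        raise ValueError(
            f"electrodes present in one condition only: {sorted(only)}")
    electrodes = ec[0].electrodes
    test = paired_test if config.paired else mww_test
    if config.paired and len(ec) != len(eo):
        raise ValueError("paired mode requires equal numbers of EC and EO recordings")
    log.info("electrode comparison: %d electrodes, %d EC / %d EO recordings, "
             "%s, grid %s", len(electrodes), len(ec), len(eo),
             "paired" if config.paired else "unpaired", list(config.xis))

    rows = []
    ncse_cmps: dict[str, list[GroupComparison]] = {}
    mse_cmps: dict[str, list[GroupComparison]] = {}
    mse_values: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if config.include_mse:
        mparams = config.mse_params()
        for name in electrodes:
            a = np.array([mse_curve(r.channels[name], mparams).values for r in ec])
            b = np.array([mse_curve(r.channels[name], mparams).values for r in eo])
            mse_values[name] = (a, b)

    for name in electrodes:
        cmps = []
        for xi in config.xis:
            a = _per_subject_ncse(ec, name, xi, config)
            b = _per_subject_ncse(eo, name, xi, config)
            cmps.append(test(a, b, name_a="EC", name_b="EO"))
        ncse_cmps[name] = cmps
        best = best_setting(config.xis, cmps)
        ranges = significant_ranges(config.xis, [c.p_value for c in cmps])
        row = {
            "electrode": name,
            "ncse_median_ec": best.max_median_a,
            "ncse_median_eo": best.max_median_b,
            "ncse_min_p": best.comparison.p_value,
            "ncse_best_xi": best.setting,
            "ncse_tier": "ns" if best.ns else best.comparison.tier,
            "ncse_sig_ranges": _format_ranges(ranges),
        }
        if config.include_mse:
            a, b = mse_values[name]
            scmps, ssettings = [], []
            for j, scale in enumerate(config.mse_scales):
                va, vb = a[:, j], b[:, j]
                if np.isnan(va).any() or np.isnan(vb).any():
                    continue  # undefined entropy at this scale for some subject
                scmps.append(test(va, vb, name_a="EC", name_b="EO"))
                ssettings.append(float(scale))
            mse_cmps[name] = scmps
            if scmps:
                sbest = best_setting(ssettings, scmps)
                sranges = significant_ranges(ssettings,
                                             [c.p_value for c in scmps])
                row.update({
                    "mse_median_ec": sbest.max_median_a,
                    "mse_median_eo": sbest.max_median_b,
                    "mse_min_p": sbest.comparison.p_value,
                    "mse_best_scale": sbest.setting,
                    "mse_tier": "ns" if sbest.ns else sbest.comparison.tier,
                    "mse_sig_ranges": _format_ranges(sranges),
                })
            else:
                row.update({"mse_median_ec": np.nan, "mse_median_eo": np.nan,
                            "mse_min_p": np.nan, "mse_best_scale": np.nan,
                            "mse_tier": "NA", "mse_sig_ranges": ""})
        rows.append(row)

    table = pd.DataFrame(rows)
    result = Table2Result(table=table, ncse_comparisons=ncse_cmps,
                          mse_comparisons=mse_cmps, config=config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_display_and_sidecar(table, out, "electrode_comparison")
        _write_manifest(config, out, {"analysis": "electrode_comparison",
                                      "n_ec": len(ec), "n_eo": len(eo)})
    return result


def _format_ranges(ranges: Sequence[tuple[float, float]]) -> str:
    def fmt(v: float) -> str:
        return f"{v:g}"

    return "; ".join(f"{fmt(lo)}-{fmt(hi)}" if lo != hi else fmt(lo)
                     for lo, hi in ranges)


def export_topomap_table(values: Mapping[str, float],
                         montage: Optional[Montage],
                         path: Union[str, Path]) -> pd.DataFrame:
    """Write electrode, head-plane x/y and value as TSV, the input of any
    external topographic-map renderer (rendering itself is out of scope)."""
    if montage is None:
        montage = load_montage()
    rows = []
    for name, value in values.items():
        x, y = montage.position(name)  # KeyError for unknown electrodes
        rows.append({"electrode": name, "x": x, "y": y, "value": float(value)})
    df = pd.DataFrame(rows, columns=["electrode", "x", "y", "value"])
    write_table(df, path)
    return df
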