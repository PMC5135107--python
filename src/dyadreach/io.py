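"""Plain-text readers and writers for every artifact the pipeline produces.

All files are delimited text with ``# key=value`` comment headers so
that runs are diffable; every writer embeds the configuration hash and
seed it was produced under.  Floats are written with a fixed format,
making outputs byte-reproducible for identical inputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .errors import DataFileError
from .identify import BlockStatistics, IdentifiedPlan
from .preprocess import TrialRecording
from .wavelet_anova import CoefficientAnovaResult, DifferenceCurveSet, PosthocResult

__all__ = [
    "config_hash",
    "write_trial",
    "read_trial",
    "write_manifest",
    "read_trials",
    "write_block_statistics",
    "read_block_statistics",
    "write_trace",
    "write_identified_plan",
    "write_anova_report",
    "write_difference_curves",
    "read_config",
    "write_config",
]

_FLOAT_FMT = "%.10g"


def config_hash(config: dict) -> str:
    """Short stable hash of a flat configuration mapping."""
    canon = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _header_lines(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in meta.items()]


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line[1:].strip()
        if "=" in body:
            k, _, v = body.partition("=")
            meta[k.strip()] = v.strip()
    return meta


def write_trial(path, rec: TrialRecording, meta: dict | None = None) -> None:
    """Write one raw trial as time/angle1/angle2/torque columns."""
    path = Path(path)
    meta = {
        "dyad_id": rec.dyad_id,
        "block_label": rec.block_label,
        "trial_index": rec.trial_index,
        "sample_rate": rec.sample_rate,
        **(meta or {}),
    }
    lines = _header_lines(meta)
    lines.append("time_s,angle1_deg,angle2_deg,torque_Nm")
    t = rec.time
    for i in range(len(rec)):
        lines.append(
            ",".join(
                _FLOAT_FMT % v
                for v in (t[i], rec.angle1[i], rec.angle2[i], rec.interaction_torque[i])
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_trial(path) -> TrialRecording:
    """Read a raw trial file, validating columns and time monotonicity."""
    path = Path(path)
    if not path.exists():
        raise DataFileError(f"trial file not found: {path}")
    header, rows = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise DataFileError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise DataFileError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise DataFileError(f"{path}: no data rows")
    data = np.array(rows)
    dt = np.diff(data[:, 0])
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise DataFileError(
            f"{path}: time column not strictly increasing at data row {bad[0] + 2}"
        )
    meta = _parse_header(header)
    return TrialRecording(
        angle1=data[:, 1],
        angle2=data[:, 2],
        interaction_torque=data[:, 3],
        sample_rate=float(meta.get("sample_rate", 100.0)),
        dyad_id=meta.get("dyad_id", "unknown"),
        block_label=meta.get("block_label", "coupled"),
        trial_index=int(meta.get("trial_index", 1)),
    )


def write_manifest(path, trial_files: list[str], meta: dict | None = None) -> None:
    """Write a manifest listing trial files in chronological order."""
    path = Path(path)
    lines = _header_lines(meta or {}) + list(trial_files)
    path.write_text("\n".join(lines) + "\n")


def read_trials(manifest_path) -> list[TrialRecording]:
    """Read all trials referenced by a manifest, in manifest order."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataFileError(f"manifest not found: {manifest_path}")
    trials = []
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trial_path = manifest_path.parent / line
        if not trial_path.exists():
            raise DataFileError(f"manifest references missing file: {trial_path}")
        trials.append(read_trial(trial_path))
    return trials


def write_block_statistics(path, stats: BlockStatistics, meta: dict | None = None) -> None:
    path = Path(path)
    meta = {
        "n_trials": stats.n_trials,
        "block_label": stats.block_label,
        **(meta or {}),
    }
    lines = _header_lines(meta)
    lines.append("mean_angle,mean_torque,var_angle,var_torque")
    for i in range(len(stats)):
        lines.append(
            ",".join(
                _FLOAT_FMT % v
                for v in (
                    stats.mean_angle[i],
                    stats.mean_torque[i],
                    stats.var_angle[i],
                    stats.var_torque[i],
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_block_statistics(path) -> BlockStatistics:
    path = Path(path)
    if not path.exists():
        raise DataFileError(f"block statistics file not found: {path}")
    header, rows = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            header.append(line)
            continue
        if line.startswith("mean_angle"):
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise DataFileError(f"{path}:{lineno}: expected 4 columns")
        rows.append([float(p) for p in parts])
    data = np.array(rows)
    meta = _parse_header(header)
    return BlockStatistics(
        mean_angle=data[:, 0],
        mean_torque=data[:, 1],
        var_angle=data[:, 2],
        var_torque=data[:, 3],
        n_trials=int(meta.get("n_trials", 30)),
        block_label=meta.get("block_label", "coupled"),
    )


def write_trace(path, trace, meta: dict | None = None) -> None:
    """Export a simulation trace with the documented column layout."""
    path = Path(path)
    lines = _header_lines(meta or {})
    two = trace.n_partners == 2
    lines.append(
        "time_s,theta1_deg,theta2_deg,dtheta1,dtheta2,tau_interaction_Nm,u1,u2"
    )
    s1 = trace.states[0]
    s2 = trace.states[1] if two else np.full_like(s1, np.nan)
    u1 = trace.commands[0]
    u2 = trace.commands[1] if two else np.full_like(u1, np.nan)
    for i in range(len(trace.time)):
        ui1 = u1[i] if i < len(u1) else np.nan
        ui2 = u2[i] if i < len(u2) else np.nan
        lines.append(
            ",".join(
                _FLOAT_FMT % v
                for v in (
                    trace.time[i], s1[i, 0], s2[i, 0], s1[i, 1], s2[i, 1],
                    trace.interaction_torque[i], ui1, ui2,
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def write_identified_plan(path, result: IdentifiedPlan, meta: dict | None = None) -> None:
    """Write the identified plans, the metric, and the full search path."""
    path = Path(path)
    meta = dict(meta or {})
    for i, plan in enumerate((result.plan1, result.plan2), start=1):
        meta[f"q_pos{i}"] = _FLOAT_FMT % plan.q_pos
        meta[f"q_vel{i}"] = _FLOAT_FMT % plan.q_vel
        meta[f"theta{i}"] = _FLOAT_FMT % plan.theta_target
    meta["fit_metric"] = _FLOAT_FMT % result.fit_metric
    lines = _header_lines(meta)
    lines.append("iteration,q_pos1,q_vel1,theta1,q_pos2,q_vel2,theta2,metric")
    for it, (params, m) in enumerate(result.search_path):
        lines.append(
            f"{it}," + ",".join(_FLOAT_FMT % v for v in params) + "," + _FLOAT_FMT % m
        )
    path.write_text("\n".join(lines) + "\n")


def write_anova_report(
    path,
    anova: CoefficientAnovaResult,
    posthoc: PosthocResult | None = None,
    curves: DifferenceCurveSet | None = None,
    meta: dict | None = None,
) -> None:
    """Coefficient table plus a pairwise significant-window summary."""
    path = Path(path)
    meta = {
        "alpha": anova.alpha,
        "df": f"{anova.df[0]};{anova.df[1]}",
        "n_significant_F": anova.n_significant,
        **(meta or {}),
    }
    if posthoc is not None:
        meta["bonferroni_m"] = posthoc.n_omnibus_significant
        meta["adjusted_alpha"] = (
            "none" if posthoc.adjusted_alpha is None
            else _FLOAT_FMT % posthoc.adjusted_alpha
        )
    lines = _header_lines(meta)
    if curves is not None:
        for (b1, b2), wins in zip(curves.pairs, curves.windows):
            if wins:
                spans = ", ".join(f"{a:.2f}-{b:.2f} s" for a, b in wins)
                lines.append(f"# Bin {b1} - Bin {b2} ({spans})")
        if not any(curves.windows):
            lines.append("# no significant bin-pair differences")
    lines.append("coefficient,F,p,significant")
    for i in range(len(anova.F)):
        lines.append(
            f"{i},{_FLOAT_FMT % anova.F[i]},{_FLOAT_FMT % anova.p[i]},"
            f"{int(anova.significant[i])}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_difference_curves(path, curves: DifferenceCurveSet, pair_index: int,
                            meta: dict | None = None) -> None:
    """One bin pair's difference curves: raw, wavelet-masked, point-wise-masked."""
    path = Path(path)
    b1, b2 = curves.pairs[pair_index]
    meta = {"bin_pair": f"{b1}-{b2}", **(meta or {})}
    lines = _header_lines(meta)
    has_pw = curves.pointwise_significant is not None
    lines.append(
        "time_s,mean_difference,wavelet_significant"
        + (",pointwise_significant" if has_pw else "")
    )
    for i in range(len(curves.time)):
        vals = [
            curves.time[i],
            curves.mean_difference[pair_index, i],
            curves.wavelet_significant[pair_index, i],
        ]
        if has_pw:
            vals.append(curves.pointwise_significant[pair_index, i])
        lines.append(",".join(_FLOAT_FMT % v for v in vals))
    path.write_text("\n".join(lines) + "\n")


def write_config(path, config: dict) -> None:
    path = Path(path)
    lines = [f"{k}={config[k]}" for k in sorted(config)]
    path.write_text("\n".join(lines) + "\n")


def read_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataFileError(f"config file not found: {path}")
    config = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DataFileError(f"{path}:{lineno}: expected key=value")
        k, _, v = line.partition("=")
        config[k.strip()] = v.strip()
    return config
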