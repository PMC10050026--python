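"""Run the population x pose grid and produce the tidy measurement table.

The full default experiment is 60 limbs x 28 poses = 1680 simulated
radiographs. Each limb is first canonicalized (mirrored into the
+x-lateral frame if left, anatomical frame established via the epicondylar
cylinder fit, normalized to neutral), then every pose on the grid is applied
and measured; deltas are taken against the same limb's zero-pose row, which
is therefore exactly zero.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LimbprojError, ValidationError
from .frame import canonicalize
from .limb_model import LimbModel, PopulationSpec
from .measure import PARAMETERS, MeasurementRecord, measure_all
from .pose import Pose, SimOptions, apply_pose, enumerate_poses

COLUMNS = ("patient_id", "side", "rotation_deg", "flexion_deg",
           "hka", "mpta", "mldfa", "mad", "d_hka", "d_mpta", "d_mldfa", "d_mad")


def _version() -> str:
    try:
        return importlib.metadata.version("limbproj")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


@dataclass
class MeasurementTable:
    """Tidy measurement table plus the provenance needed to reproduce it."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        """Write UTF-8 comma-separated output with '#'-commented provenance."""
        path = Path(path)
        lines = [f"# {k}: {v}" for k, v in self.provenance.items()]
        with path.open("w", encoding="utf-8") as fh:
            for line in lines:
                fh.write(line + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "MeasurementTable":
        path = Path(path)
        prov = {}
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition(":")
                prov[key.strip()] = val.strip()
        data = pd.read_csv(path, comment="#")
        missing = [c for c in COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"measurement CSV missing columns: {missing}")
        return cls(data=data, provenance=prov)


def run_experiment(
    population: list[LimbModel],
    poses: list[Pose] | None = None,
    opts: SimOptions | None = None,
    knee_centre: str = "fnp",
    spec: PopulationSpec | None = None,
) -> MeasurementTable:
    """Measure every limb in every pose; deterministic given the population."""
    if not population:
        raise ValidationError("population is empty")
    poses = poses if poses is not None else enumerate_poses()
    opts = opts or SimOptions()
    records: list[MeasurementRecord] = []
    for limb in population:
        try:
            canon = canonicalize(limb)
            zero = measure_all(apply_pose(canon, Pose(0, 0), opts), knee_centre)
            for pose in poses:
                vals = measure_all(apply_pose(canon, pose, opts), knee_centre)
                records.append(MeasurementRecord(
                    patient_id=limb.patient_id,
                    side=limb.side,
                    rotation_deg=pose.rotation_deg,
                    flexion_deg=pose.flexion_deg,
                    **vals,
                    **{f"d_{k}": vals[k] - zero[k] for k in PARAMETERS},
                ))
        except LimbprojError as exc:
            raise type(exc)(
                f"limb {limb.patient_id}/{limb.side}: {exc}") from exc
    data = pd.DataFrame([asdict(r) for r in records], columns=list(COLUMNS))
    provenance = {
        "package": f"limbproj {_version()}",
        "n_limbs": len(population),
        "n_poses": len(poses),
        "knee_centre": knee_centre,
        "sim_options": asdict(opts),
    }
    if spec is not None:
        provenance["population_spec"] = asdict(spec)
        provenance["seed"] = spec.seed
    return MeasurementTable(data=data, provenance=provenance)


def _require_complete(table: MeasurementTable | pd.DataFrame) -> pd.DataFrame:
    df = table.data if isinstance(table, MeasurementTable) else table
    counts = df.groupby(["patient_id", "side"]).size()
    n_poses = df[["rotation_deg", "flexion_deg"]].drop_duplicates().shape[0]
    if counts.nunique() != 1 or counts.iloc[0] != n_poses:
        raise ValidationError("incomplete pose grid: unequal rows per limb")
    dup = df.duplicated(subset=["patient_id", "side", "rotation_deg", "flexion_deg"])
    if dup.any():
        raise ValidationError("duplicate (limb, pose) rows")
    return df


def descriptive_deltas(table: MeasurementTable | pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and SD of each delta, indexed by (rotation, flexion)."""
    df = _require_complete(table)
    agg = df.groupby(["rotation_deg", "flexion_deg"])[
        [f"d_{p}" for p in PARAMETERS]].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg


def neutral_summary(table: MeasurementTable | pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/min/max of the four parameters in the zero position."""
    df = table.data if isinstance(table, MeasurementTable) else table
    zero = df[(df.rotation_deg == 0) & (df.flexion_deg == 0)]
    return zero[list(PARAMETERS)].agg(["mean", "std", "min", "max"])


def plot_delta_curves(table: MeasurementTable | pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Minimal mean-delta-vs-rotation plots, one panel per parameter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _require_complete(table)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    units = {"hka": "deg", "mpta": "deg", "mldfa": "deg", "mad": "mm"}
    for p in PARAMETERS:
        fig, ax = plt.subplots(figsize=(5, 4))
        for f, sub in df.groupby("flexion_deg"):
            cell = sub.groupby("rotation_deg")[f"d_{p}"].mean()
            ax.plot(cell.index, cell.values, marker="o", label=f"flexion {f} deg")
        ax.set_xlabel("axial rotation (deg, + = external)")
        ax.set_ylabel(f"mean change in {p.upper()} ({units[p]})")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"delta_{p}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
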