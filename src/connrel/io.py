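"""Plain-text (TSV/JSON) persistence for cohorts, parcellations, connectomes.

Layout of a cohort directory (one per atlas)::

    <dir>/
      parcellation.tsv            # node_id, network, coverage
      manifest.tsv                # subject, session, group, path
      <subject>_ses-<s>/
        signals.tsv               # T rows x N labeled columns
        motion.tsv                # trans_x..trans_z, rot_x..rot_z
        nuisance.tsv              # global, wm, csf

Connectomes are labeled TSV matrices with literal ``NaN`` for missing values
and a JSON sidecar carrying provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Parcellation, ParcellatedRun
from .connectome import Connectome

_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
_NUISANCE_COLS = ["global", "wm", "csf"]
_FLOAT_FMT = "%.8g"


def write_parcellation(parcellation: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "node_id": parcellation.node_ids,
            "network": [parcellation.network_of[n] for n in parcellation.node_ids],
            "coverage": [parcellation.coverage_of[n] for n in parcellation.node_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_parcellation(path: str | Path, atlas_name: str | None = None) -> Parcellation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "network": str})
    if atlas_name is None:
        atlas_name = path.parent.name if path.name == "parcellation.tsv" else path.stem
    return Parcellation(
        node_ids=tuple(df["node_id"]),
        network_of=dict(zip(df["node_id"], df["network"])),
        coverage_of=dict(zip(df["node_id"], df["coverage"].astype(float))),
        atlas_name=atlas_name,
    )


def write_cohort(
    runs: list[ParcellatedRun],
    parcellation: Parcellation,
    directory: str | Path,
) -> Path:
    """Write runs + parcellation + manifest under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_parcellation(parcellation, directory / "parcellation.tsv")
    records = []
    for run in runs:
        run_dir = directory / f"{run.subject_id}_ses-{run.session}"
        run_dir.mkdir(exist_ok=True)
        pd.DataFrame(run.signals, columns=list(parcellation.node_ids)).to_csv(
            run_dir / "signals.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        pd.DataFrame(run.motion_params, columns=_MOTION_COLS).to_csv(
            run_dir / "motion.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        pd.DataFrame(run.nuisance, columns=_NUISANCE_COLS).to_csv(
            run_dir / "nuisance.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        records.append(
            {
                "subject": run.subject_id,
                "session": run.session,
                "group": run.group,
                "tr_seconds": run.tr_seconds,
                "path": run_dir.name,
            }
        )
    pd.DataFrame(records).to_csv(
        directory / "manifest.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    return directory


def read_cohort(directory: str | Path) -> list[ParcellatedRun]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    runs = []
    for rec in manifest.itertuples():
        run_dir = directory / str(rec.path)
        signals = pd.read_csv(run_dir / "signals.tsv", sep="\t").to_numpy(float)
        motion = pd.read_csv(run_dir / "motion.tsv", sep="\t").to_numpy(float)
        nuisance = pd.read_csv(run_dir / "nuisance.tsv", sep="\t").to_numpy(float)
        runs.append(
            ParcellatedRun(
                subject_id=str(rec.subject),
                session=int(rec.session),
                group=str(rec.group),
                signals=signals,
                motion_params=motion,
                nuisance=nuisance,
                tr_seconds=float(rec.tr_seconds),
            )
        )
    return runs


def write_connectome(conn: Connectome, path: str | Path) -> Path:
    """Labeled TSV matrix with NaN literals plus a provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(conn.z, index=list(conn.node_ids), columns=list(conn.node_ids))
    # full precision so a written connectome round-trips bit-exactly
    df.to_csv(path, sep="\t", na_rep="NaN", float_format="%.17g")
    sidecar = {
        "subject": conn.subject_id,
        "session": conn.session,
        "group": conn.group,
        "atlas": conn.atlas_name,
        "variant": conn.variant,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_connectome(path: str | Path) -> Connectome:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Connectome(
        z=df.to_numpy(float),
        node_ids=tuple(str(c) for c in df.columns),
        atlas_name=str(meta.get("atlas", "")),
        subject_id=str(meta.get("subject", "")),
        session=int(meta.get("session", 0)),
        group=str(meta.get("group", "")),
        variant=str(meta.get("variant", "")),
    )
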