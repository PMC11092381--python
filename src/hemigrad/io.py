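"""Plain-text cohort I/O.

All interchange is TSV/CSV/JSON with explicit headers: a cohort directory
holds ``parcellation.tsv``, ``phenotypes.csv``, one time-series TSV per
subject under ``timeseries/`` (rows = volumes, columns = regions, header
row of region ids), optional motion traces under ``motion/`` (columns
``fd``, ``dvars``), and ``ground_truth.json`` when the cohort is
synthetic. Indices are 0-based everywhere. Every file starts with a
comment line carrying the provenance stamp (seed and config hash) so a
run can be reproduced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import read_parcellation, write_parcellation
from .prep import MotionTrace
from .synth import CohortDataset, GroundTruth, SubjectRecord


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _stamp(seed=None, cfg_hash=None) -> str:
    parts = ["hemigrad"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " ".join(parts)


def write_cohort(dataset: CohortDataset, outdir, seed=None, cfg_hash=None) -> Path:
    """Write a cohort directory; returns its path."""
    out = Path(outdir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    stamp = _stamp(seed, cfg_hash)
    write_parcellation(dataset.parcellation, out / "parcellation.tsv", stamp)
    ph = dataset.phenotypes()
    ph["tr"] = [s.tr for s in dataset.subjects]
    with open(out / "phenotypes.csv", "w") as fh:
        fh.write(f"# {stamp}\n")
        ph.to_csv(fh, index=False)
    region_ids = dataset.parcellation.region_ids()
    has_motion = any(s.motion is not None for s in dataset.subjects)
    if has_motion:
        (out / "motion").mkdir(exist_ok=True)
    for s in dataset.subjects:
        df = pd.DataFrame(s.timeseries, columns=region_ids)
        with open(out / "timeseries" / f"{s.subject_id}.tsv", "w") as fh:
            fh.write(f"# {stamp}\n")
            df.to_csv(fh, sep="\t", index=False)
        if s.motion is not None:
            mdf = pd.DataFrame({"fd": s.motion.fd, "dvars": s.motion.dvars})
            with open(out / "motion" / f"{s.subject_id}.tsv", "w") as fh:
                fh.write(f"# {stamp}\n")
                mdf.to_csv(fh, sep="\t", index=False)
    if dataset.ground_truth is not None:
        (out / "ground_truth.json").write_text(dataset.ground_truth.to_json())
    return out


def read_cohort(cohort_dir) -> CohortDataset:
    """Read and validate a cohort directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    parc = read_parcellation(d / "parcellation.tsv")
    ph = pd.read_csv(d / "phenotypes.csv", comment="#")
    required = {"subject_id", "group", "site", "age", "sex", "mean_fd", "bdi"}
    missing = required - set(ph.columns)
    if missing:
        raise ValueError(f"phenotypes.csv missing columns: {sorted(missing)}")
    truth = None
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        truth = GroundTruth.from_json(gt_path.read_text())
    subjects = []
    missing_ts = [
        sid for sid in ph["subject_id"]
        if not (d / "timeseries" / f"{sid}.tsv").exists()
    ]
    if missing_ts:
        raise FileNotFoundError(
            f"phenotype rows without a time-series file: {missing_ts}"
        )
    for row in ph.itertuples(index=False):
        ts = pd.read_csv(
            d / "timeseries" / f"{row.subject_id}.tsv", sep="\t", comment="#"
        )
        if ts.columns.tolist() != parc.region_ids():
            raise ValueError(
                f"subject {row.subject_id}: time-series columns do not match "
                "the parcellation region order"
            )
        tr = float(getattr(row, "tr", 2.5))
        motion = None
        mpath = d / "motion" / f"{row.subject_id}.tsv"
        if mpath.exists():
            mdf = pd.read_csv(mpath, sep="\t", comment="#")
            motion = MotionTrace(
                fd=mdf["fd"].to_numpy(), dvars=mdf["dvars"].to_numpy(), tr=tr
            )
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                site=str(row.site),
                age=float(row.age),
                sex=str(row.sex),
                mean_fd=float(row.mean_fd),
                bdi=int(row.bdi),
                timeseries=ts.to_numpy(dtype=float),
                tr=tr,
                motion=motion,
            )
        )
    return CohortDataset(subjects=subjects, parcellation=parc, ground_truth=truth)


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash=None, sep=",") -> None:
    """Write a tidy result table with the provenance stamp header."""
    with open(path, "w") as fh:
        fh.write(f"# {_stamp(seed, cfg_hash)}\n")
        df.to_csv(fh, index=False, sep=sep)


def read_table(path, sep=",") -> pd.DataFrame:
    return pd.read_csv(path, comment="#", sep=sep)


def write_matrix(M: np.ndarray, path, columns=None, seed=None, cfg_hash=None) -> None:
    cols = columns if columns is not None else [f"c{i}" for i in range(M.shape[1])]
    write_table(pd.DataFrame(M, columns=cols), path, seed, cfg_hash, sep="\t")
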