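"""Standard-format I/O: NIfTI volumes, TSV tables, JSON manifests.

Cohorts are stored as one NIfTI volume per subject plus a shared atlas
label volume; motion traces and WM/CSF ensembles are TSV with frames as
columns; feature matrices are one TSV per feature type (rows = subjects,
columns = named features, pair names "i~j" for TC and "i->j" for GC).
A JSON manifest ties each collection together and echoes the generating
configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from restcombine.features import FeatureSet, FeatureVector
from restcombine.synthetic_cohort import CohortSpec, EffectSpec, SubjectData

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_feature_sets",
    "read_feature_sets",
    "write_cv_result",
    "write_significance_table",
]

_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])  # nominal 3 mm isotropic grid


def _write_frames_tsv(path: Path, array: np.ndarray, prefix: str) -> None:
    df = pd.DataFrame(array,
                      index=[f"{prefix}{i}" for i in range(array.shape[0])],
                      columns=[f"f{t}" for t in range(array.shape[1])])
    df.to_csv(path, sep="\t", index_label="row")


def _read_frames_tsv(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col="row").to_numpy(dtype=float)


def write_cohort(subjects: list[SubjectData], spec: CohortSpec,
                 outdir: str | Path) -> Path:
    """Write a cohort directory; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas_path = outdir / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(subjects[0].atlas.astype(np.int32), _AFFINE),
             atlas_path)
    entries = []
    for s in subjects:
        bold = outdir / f"{s.subject_id}_bold.nii.gz"
        nib.save(nib.Nifti1Image(s.voxels.astype(np.float32), _AFFINE), bold)
        motion = outdir / f"{s.subject_id}_motion.tsv"
        _write_frames_tsv(motion, s.motion, "par")
        wm = outdir / f"{s.subject_id}_wm.tsv"
        _write_frames_tsv(wm, s.wm_ensemble, "wm")
        csf = outdir / f"{s.subject_id}_csf.tsv"
        _write_frames_tsv(csf, s.csf_ensemble, "csf")
        entries.append({
            "subject_id": s.subject_id,
            "label": int(s.label),
            "bold": bold.name,
            "motion": motion.name,
            "wm": wm.name,
            "csf": csf.name,
        })
    spec_echo = dataclasses.asdict(spec)
    spec_echo["effects"] = [dataclasses.asdict(e) for e in spec.effects]
    manifest = {
        "atlas": atlas_path.name,
        "subjects": entries,
        "spec": spec_echo,
        "seed": spec.seed,
    }
    path = outdir / "cohort.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_cohort(manifest_path: str | Path) -> tuple[list[SubjectData], dict]:
    """Read a cohort directory back into memory."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    atlas = np.asarray(nib.load(root / manifest["atlas"]).dataobj,
                       dtype=np.int32)
    subjects = []
    for e in manifest["subjects"]:
        bold = root / e["bold"]
        if not bold.exists():
            raise FileNotFoundError(f"missing volume: {bold}")
        for key in ("motion", "wm", "csf"):
            if not (root / e[key]).exists():
                raise FileNotFoundError(f"missing {key} TSV: {root / e[key]}")
        subjects.append(SubjectData(
            subject_id=e["subject_id"],
            label=int(e["label"]),
            voxels=np.asarray(nib.load(bold).dataobj, dtype=float),
            atlas=atlas,
            motion=_read_frames_tsv(root / e["motion"]),
            wm_ensemble=_read_frames_tsv(root / e["wm"]),
            csf_ensemble=_read_frames_tsv(root / e["csf"]),
        ))
    return subjects, manifest["spec"]


def write_feature_sets(feature_sets: list[FeatureSet],
                       outdir: str | Path, params: dict | None = None) -> Path:
    """One TSV per feature type plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    types = list(feature_sets[0].features.keys())
    files = {}
    for ft in types:
        names = feature_sets[0].features[ft].names
        rows = {fs.subject_id: fs.features[ft].values for fs in feature_sets}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
        fname = f"features_{ft}.tsv"
        df.to_csv(outdir / fname, sep="\t", index_label="subject_id")
        files[ft] = fname
    manifest = {
        "feature_types": types,
        "files": files,
        "labels": {fs.subject_id: int(fs.label) for fs in feature_sets},
        "params": params or {},
    }
    path = outdir / "features.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_feature_sets(manifest_path: str | Path) -> list[FeatureSet]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    frames = {ft: pd.read_csv(root / fname, sep="\t", index_col="subject_id")
              for ft, fname in manifest["files"].items()}
    subject_ids = list(next(iter(frames.values())).index)
    out = []
    for sid in subject_ids:
        feats = {
            ft: FeatureVector(
                feature_type=ft,
                names=tuple(df.columns),
                values=df.loc[sid].to_numpy(dtype=float),
            )
            for ft, df in frames.items()
        }
        out.append(FeatureSet(subject_id=sid,
                              label=int(manifest["labels"][sid]),
                              features=feats))
    return out


def write_cv_result(result, path: str | Path) -> None:
    """Serialise a CVResult (metrics, pooled counts, per-fold detail)."""
    m = result.metrics
    payload = {
        "framework": result.framework,
        "seed": result.seed,
        "config": _jsonable(result.config),
        "pooled_counts": dataclasses.asdict(result.pooled),
        "metrics": dataclasses.asdict(m),
        "folds": [
            {
                "counts": dataclasses.asdict(c),
                "selection": {
                    ft: {
                        "percent": sel.percent,
                        "acc_m": sel.acc_m,
                        "c": sel.c,
                        "gamma": sel.gamma,
                        "kept_indices": [int(i) for i in sel.kept_indices],
                    }
                    for ft, sel in sels.items()
                },
                "beta": (None if w is None else [float(b) for b in w.beta]),
            }
            for c, sels, w in zip(result.fold_counts, result.selections,
                                  result.weights)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_significance_table(sig, names, path: str | Path) -> None:
    """TSV of per-feature observed counts, threshold and significance."""
    df = pd.DataFrame({
        "feature": list(names),
        "observed_count": sig.observed_counts,
        "threshold": sig.threshold,
        "significant": sig.significant.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
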