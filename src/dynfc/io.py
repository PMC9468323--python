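"""File formats: NIfTI volumes, label tables, feature archives, manifests.

Voxel data travel as 4D NIfTI (x, y, z, t) flattened to (T, V) in C order of
the masked grid; features and maps as compressed ``.npz`` archives with a
small metadata header; subject labels as a two-column tab-separated table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

ARCHIVE_VERSION = 1

__all__ = [
    "save_nifti_series", "load_nifti_series", "save_label_table",
    "load_label_table", "save_features", "load_features", "save_cohort",
    "load_cohort", "write_manifest",
]


def save_nifti_series(path, series, grid_shape, affine=None):
    """Write a (T, V) series as a 4D NIfTI on the given grid."""
    series = np.asarray(series)
    T = series.shape[0]
    vol = series.T.reshape(*grid_shape, T)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
             str(path))


def load_nifti_series(path, mask=None):
    """Load a 4D NIfTI into a (T, V) matrix.

    Voxels are flattened in C order of the (x, y, z) grid, restricted to
    ``mask`` (a boolean 3D array or a 3D mask NIfTI path) when given.

    Returns
    -------
    series : (T, V) float64 array
    geometry : dict with grid shape, affine, and the flat mask indices.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
    grid = data.shape[:3]
    if mask is not None:
        if isinstance(mask, (str, Path)):
            mimg = nib.load(str(mask))
            if mimg.shape != grid:
                raise ValueError("mask grid does not match the data grid")
            if not np.allclose(mimg.affine, img.affine, atol=1e-4):
                raise ValueError("mask affine does not match the data affine")
            mask = np.asarray(mimg.dataobj) > 0
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid:
            raise ValueError("mask shape does not match the data grid")
    else:
        mask = np.ones(grid, dtype=bool)
    flat_idx = np.flatnonzero(mask.reshape(-1))
    series = data.reshape(-1, data.shape[3])[flat_idx].T
    geometry = {"grid_shape": grid, "affine": img.affine,
                "mask_indices": flat_idx}
    return series, geometry


def save_label_table(path, subject_ids, groups):
    pd.DataFrame({"subject_id": subject_ids, "group": groups}).to_csv(
        path, sep="\t", index=False)


def load_label_table(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"label table lacks columns: {sorted(missing)}")
    return df["subject_id"].tolist(), df["group"].to_numpy()


def save_features(path, sequences, subject_ids, level, width, step, tr):
    """Archive a set of per-subject feature arrays with their metadata."""
    payload = {f"seq_{i:05d}": np.asarray(s) for i, s in enumerate(sequences)}
    meta = dict(version=ARCHIVE_VERSION, level=level, width=width, step=step,
                tr=tr, subject_ids=list(subject_ids))
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_features(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta.get("version") != ARCHIVE_VERSION:
            raise ValueError("unsupported feature-archive version")
        n = len(meta["subject_ids"])
        seqs = [z[f"seq_{i:05d}"] for i in range(n)]
    return seqs, meta


def save_cohort(outdir, cohort, as_nifti=False):
    """Persist a synthetic cohort: data, labels, and the generating truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_label_table(outdir / "labels.tsv", cohort.subject_ids,
                     cohort.group_labels)
    if as_nifti:
        for sid, series in zip(cohort.subject_ids, cohort.voxel_series):
            save_nifti_series(outdir / f"{sid}_bold.nii.gz", series,
                              cohort.grid_shape)
    else:
        np.savez_compressed(
            outdir / "voxel_series.npz",
            **{sid: s.astype(np.float32)
               for sid, s in zip(cohort.subject_ids, cohort.voxel_series)})
    np.savez_compressed(
        outdir / "ground_truth.npz",
        spatial_maps=cohort.spatial_maps,
        state_sequences=np.stack(cohort.state_sequences),
        group_labels=cohort.group_labels,
        delta=cohort.delta,
        snr=np.array(cohort.snr),
        seed=np.array(cohort.seed),
        grid_shape=np.array(cohort.grid_shape),
        effect_pairs=np.array(cohort.effect_pairs, dtype=int),
        **{f"cov_{g}": c for g, c in cohort.state_covariances.items()})


def load_cohort(outdir):
    """Load the voxel data and labels written by :func:`save_cohort`."""
    outdir = Path(outdir)
    subject_ids, groups = load_label_table(outdir / "labels.tsv")
    npz = outdir / "voxel_series.npz"
    if npz.exists():
        with np.load(npz) as z:
            series = [np.asarray(z[sid], dtype=np.float64)
                      for sid in subject_ids]
    else:
        series = []
        for sid in subject_ids:
            s, _ = load_nifti_series(outdir / f"{sid}_bold.nii.gz")
            series.append(s)
    return series, subject_ids, groups


def write_manifest(path, config_dict, seed, warnings_list=()):
    """Reproducibility record: config hash, seed, package versions."""
    import sklearn
    import scipy

    from . import __version__
    cfg_json = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "versions": {"dynfc": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__},
        "warnings": list(warnings_list),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
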