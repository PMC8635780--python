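"""Readers, writers and dataset-manifest handling.

Conventions: world coordinates are MNI-style mm; voxel indices are
0-based and the affine maps voxel centres; tables are UTF-8 TSV with
'.' decimal; volumes are NIfTI-1; meshes GIFTI (with an OFF fallback);
audits JSON.  A dataset directory is tied together by ``manifest.json``
naming the seed, parameters and per-subject files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    BoldRun,
    RegionThicknessTable,
    SubjectMeta,
    SurfaceMesh,
    ThicknessDataset,
    meta_frame,
)

__all__ = [
    "write_tsv",
    "write_mesh_gifti",
    "read_mesh_gifti",
    "write_mesh_off",
    "read_mesh_off",
    "write_dataset",
    "load_cohort",
]

_FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> None:
    """Deterministic TSV writer (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_mesh_gifti(mesh: SurfaceMesh, path) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def read_mesh_gifti(path) -> SurfaceMesh:
    img = nib.load(str(path))
    verts = tris = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(da.data, dtype=np.int64)
    if verts is None or tris is None:
        raise ValueError(f"{path} lacks pointset/triangle arrays")
    return SurfaceMesh(vertices=verts, triangles=tris)


def write_mesh_off(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh_off(path) -> SurfaceMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError(f"{path} is not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4:], dtype=float)
    verts = data[: nv * 3].reshape(nv, 3)
    rest = data[nv * 3:]
    faces = rest.reshape(nf, 4)[:, 1:].astype(np.int64)
    return SurfaceMesh(vertices=verts, triangles=faces)


def _meta_from_frame(df: pd.DataFrame) -> list[SubjectMeta]:
    subs = []
    for row in df.itertuples(index=False):
        dep = None if pd.isna(row.deprivation_days) else float(row.deprivation_days)
        acu = None if pd.isna(row.acuity) else float(row.acuity)
        subs.append(SubjectMeta(id=str(row.id), group=str(row.group),
                                age=float(row.age), sex=str(row.sex),
                                deprivation_days=dep, acuity=acu))
    return subs


def _write_bold(run: BoldRun, stem: Path) -> dict:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms((*np.abs(np.diag(run.affine))[:3], run.tr))
    nib.save(img, str(stem) + "_bold.nii")
    nib.save(nib.Nifti1Image(run.mask.astype(np.uint8), run.affine),
             str(stem) + "_mask.nii")
    write_tsv(pd.DataFrame(run.motion,
                           columns=["tx", "ty", "tz", "rx", "ry", "rz"]),
              str(stem) + "_motion.tsv")
    write_tsv(pd.DataFrame({"wm": run.wm, "csf": run.csf,
                            "global": run.global_signal}),
              str(stem) + "_tissue.tsv")
    return {"id": run.subject.id, "bold": stem.name + "_bold.nii",
            "mask": stem.name + "_mask.nii",
            "motion": stem.name + "_motion.tsv",
            "tissue": stem.name + "_tissue.tsv", "tr": run.tr}


def write_dataset(outdir, seed: int, parameters: dict | None = None,
                  thickness: ThicknessDataset | None = None,
                  region_table: RegionThicknessTable | None = None,
                  bold: list[BoldRun] | None = None) -> Path:
    """Emit a dataset directory with a manifest naming seed and parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "parameters": parameters or {}}
    subjects = None
    if thickness is not None:
        subjects = thickness.subjects
        write_mesh_gifti(thickness.mesh, outdir / "mesh.surf.gii")
        df = pd.DataFrame(thickness.thickness.T,
                          columns=[s.id for s in thickness.subjects])
        write_tsv(df, outdir / "thickness.tsv")
        manifest["thickness"] = {"mesh": "mesh.surf.gii",
                                 "values": "thickness.tsv"}
    if region_table is not None:
        subjects = subjects or region_table.subjects
        write_tsv(region_table.regions, outdir / "regions.tsv")
        df = pd.DataFrame(region_table.values,
                          columns=region_table.region_names)
        df.insert(0, "id", [s.id for s in region_table.subjects])
        write_tsv(df, outdir / "region_thickness.tsv")
        manifest["region_table"] = {"regions": "regions.tsv",
                                    "values": "region_thickness.tsv"}
    if bold is not None:
        subjects = subjects or [r.subject for r in bold]
        entries = []
        for run in bold:
            entries.append(_write_bold(run, outdir / run.subject.id))
        manifest["bold"] = entries
    if subjects is None:
        raise ValueError("nothing to write")
    write_tsv(meta_frame(subjects), outdir / "subjects.tsv")
    manifest["subjects"] = "subjects.tsv"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir / "manifest.json"


def load_cohort(manifest_path):
    """Load a dataset directory back into typed in-memory objects.

    Returns ``(thickness, region_table, bold_runs, subjects)`` with
    None for absent components.  Identifier mismatches, duplicate ids
    and unknown group labels are hard errors naming the offenders.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent

    def need(rel):
        p = root / rel
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
        return p

    meta = pd.read_csv(need(manifest["subjects"]), sep="\t")
    ids = list(meta["id"].astype(str))
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids in manifest: {dup}")
    subjects = _meta_from_frame(meta)
    by_id = {s.id: s for s in subjects}

    thickness = region_table = bold = None
    if "thickness" in manifest:
        mesh = read_mesh_gifti(need(manifest["thickness"]["mesh"]))
        df = pd.read_csv(need(manifest["thickness"]["values"]), sep="\t")
        missing = [c for c in df.columns if c not in by_id]
        if missing:
            raise ValueError(f"thickness table has unknown subject ids: {missing}")
        thick = df[[s.id for s in subjects]].to_numpy().T
        thickness = ThicknessDataset(mesh=mesh, subjects=subjects,
                                     thickness=thick)
    if "region_table" in manifest:
        regions = pd.read_csv(need(manifest["region_table"]["regions"]), sep="\t")
        df = pd.read_csv(need(manifest["region_table"]["values"]), sep="\t")
        vids = list(df["id"].astype(str))
        unknown = [i for i in vids if i not in by_id]
        if unknown:
            raise ValueError(f"region table has unknown subject ids: {unknown}")
        order = [vids.index(s.id) for s in subjects if s.id in vids]
        vals = df.drop(columns="id").to_numpy()[order]
        subs = [s for s in subjects if s.id in vids]
        region_table = RegionThicknessTable(subjects=subs, regions=regions,
                                            values=vals)
    if "bold" in manifest:
        bold = []
        for entry in manifest["bold"]:
            sid = str(entry["id"])
            if sid not in by_id:
                raise ValueError(f"BOLD list names unknown subject id {sid!r}")
            img = nib.load(str(need(entry["bold"])))
            mask = nib.load(str(need(entry["mask"]))).get_fdata() > 0
            motion = pd.read_csv(need(entry["motion"]), sep="\t").to_numpy()
            tissue = pd.read_csv(need(entry["tissue"]), sep="\t")
            bold.append(BoldRun(
                subject=by_id[sid], data=np.asarray(img.dataobj, dtype=float),
                tr=float(entry["tr"]), affine=img.affine, mask=mask,
                motion=motion, wm=tissue["wm"].to_numpy(),
                csf=tissue["csf"].to_numpy(),
                global_signal=tissue["global"].to_numpy()))
    return thickness, region_table, bold, subjects
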