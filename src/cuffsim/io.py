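"""HDF5 serialization for leadfields and signature datasets."""

from __future__ import annotations

import pathlib

import h5py
import numpy as np

from cuffsim.experiments import ExperimentDataset
from cuffsim.forward import Leadfield
from cuffsim.geometry import CrossSectionModel, build_fine_electrode

FORMAT_VERSION = 1


class IOError_(ValueError):
    """Unreadable or incompatible container file."""


def _check_version(handle: h5py.File, path) -> None:
    version = int(handle.attrs.get("format_version", -1))
    if version != FORMAT_VERSION:
        raise IOError_(
            f"{path}: unsupported container version {version} "
            f"(expected {FORMAT_VERSION})"
        )


def write_cross_section(
    cs: CrossSectionModel, path: str | pathlib.Path, config_hash: str = ""
) -> None:
    """Store a labeled cross-section; label codes documented in the header."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["kind"] = "cross_section"
        fh.attrs["pixel_pitch_mm"] = cs.pixel_pitch
        fh.attrs["config_hash"] = config_hash
        fh.attrs["label_codes"] = (
            "0=saline 1=endoneurium 2=perineurium 3=epineurium "
            "4=electrode 5=outside"
        )
        fh.create_dataset("label_image", data=cs.label_image, compression="gzip")
        fh.create_dataset("fascicle_ids", data=cs.fascicle_ids, compression="gzip")
        fh.create_dataset("fascicle_centroids", data=np.asarray(cs.fascicle_centroids))


def read_cross_section(
    path: str | pathlib.Path, expected_hash: str | None = None
) -> CrossSectionModel:
    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        if fh.attrs.get("kind") != "cross_section":
            raise IOError_(f"{path}: not a cross-section container")
        if expected_hash is not None and fh.attrs.get("config_hash") != expected_hash:
            raise IOError_(f"{path}: config hash mismatch")
        return CrossSectionModel(
            label_image=fh["label_image"][...],
            fascicle_ids=fh["fascicle_ids"][...],
            pixel_pitch=float(fh.attrs["pixel_pitch_mm"]),
            fascicle_centroids=[tuple(p) for p in fh["fascicle_centroids"][...]],
        )


def write_leadfield(
    leadfield: Leadfield, path: str | pathlib.Path, config_hash: str = ""
) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["kind"] = "leadfield"
        fh.attrs["referenced"] = leadfield.referenced
        fh.attrs["config_hash"] = config_hash
        fh.create_dataset("matrix", data=leadfield.matrix, compression="gzip")
        fh.create_dataset("node_fascicle", data=leadfield.node_fascicle)
        fh.create_dataset("node_iy", data=leadfield.node_iy)
        fh.create_dataset("node_ix", data=leadfield.node_ix)
        fh.create_dataset("slab_iz", data=leadfield.slab_iz)
        fh.create_dataset("slab_z", data=leadfield.slab_z)


def read_leadfield(
    path: str | pathlib.Path, expected_hash: str | None = None
) -> Leadfield:
    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        if fh.attrs.get("kind") != "leadfield":
            raise IOError_(f"{path}: not a leadfield container")
        if expected_hash is not None and fh.attrs.get("config_hash") != expected_hash:
            raise IOError_(f"{path}: config hash mismatch")
        return Leadfield(
            matrix=fh["matrix"][...],
            layout=build_fine_electrode(),
            node_fascicle=fh["node_fascicle"][...],
            node_iy=fh["node_iy"][...],
            node_ix=fh["node_ix"][...],
            slab_iz=fh["slab_iz"][...],
            slab_z=fh["slab_z"][...],
            referenced=bool(fh.attrs["referenced"]),
        )


def write_dataset(
    dataset: ExperimentDataset, path: str | pathlib.Path, config_hash: str = ""
) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["kind"] = "dataset"
        fh.attrs["n_samples"] = dataset.n_samples
        fh.attrs["noise_ratio"] = dataset.noise_ratio
        fh.attrs["seed"] = dataset.seed
        fh.attrs["config_hash"] = config_hash
        fh.create_dataset(
            "recordings",
            data=dataset.recordings,
            compression="gzip",
            chunks=(min(256, dataset.n_samples), *dataset.recordings.shape[1:]),
        )
        fh.create_dataset("labels", data=dataset.labels)
        fh.create_dataset("fascicle_ids", data=dataset.fascicle_ids)
        fh.create_dataset("sample_fascicle", data=dataset.sample_fascicle)
        fh.create_dataset("sample_node", data=dataset.sample_node)
        fh.create_dataset("sample_template", data=dataset.sample_template)


def read_dataset(
    path: str | pathlib.Path, expected_hash: str | None = None
) -> ExperimentDataset:
    with h5py.File(path, "r") as fh:
        _check_version(fh, path)
        if fh.attrs.get("kind") != "dataset":
            raise IOError_(f"{path}: not a dataset container")
        if expected_hash is not None and fh.attrs.get("config_hash") != expected_hash:
            raise IOError_(f"{path}: config hash mismatch")
        recordings = fh["recordings"][...]
        if recordings.shape[0] != int(fh.attrs["n_samples"]):
            raise IOError_(f"{path}: truncated file (sample count mismatch)")
        return ExperimentDataset(
            recordings=recordings,
            labels=fh["labels"][...],
            fascicle_ids=fh["fascicle_ids"][...],
            layout=build_fine_electrode(),
            sample_fascicle=fh["sample_fascicle"][...],
            sample_node=fh["sample_node"][...],
            sample_template=fh["sample_template"][...],
            noise_ratio=float(fh.attrs["noise_ratio"]),
            seed=int(fh.attrs["seed"]),
        )
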