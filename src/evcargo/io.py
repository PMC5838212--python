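"""File formats for the pipeline.

Counts travel as TSV (``probe_id``, ``probe_class``, one column per sample)
with a sample -> condition map in YAML; voltage traces as HDF5 (one dataset
per electrode, attributes ``sampling_rate_hz`` and ``epoch``) or long-format
CSV; UTR and miRNA sequences as FASTA; Ct tables as CSV; simulator ground
truth as JSON sidecars written next to the data file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import CtTable, MiRNACountMatrix
from .mea import ElectrodeRecording

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_conditions_yaml",
    "read_conditions_yaml",
    "write_recordings_hdf5",
    "read_recordings_hdf5",
    "write_recordings_csv",
    "read_recordings_csv",
    "write_fasta",
    "read_fasta",
    "write_ct_csv",
    "read_ct_csv",
    "truth_sidecar_path",
    "write_truth_json",
]


# ---------------------------------------------------------------------------
# counts


def write_counts_tsv(m: MiRNACountMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = m.values.copy()
    out.insert(0, "probe_class", m.probe_class.loc[out.index])
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    return path


def read_counts_tsv(
    path: str | Path,
    conditions: Mapping[str, str] | str | Path,
    state: str = "raw",
) -> MiRNACountMatrix:
    """``conditions`` is a sample->condition mapping or a YAML path."""
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    if "probe_class" not in df.columns:
        raise ValueError("counts TSV must have a probe_class column")
    probe_class = df.pop("probe_class")
    df.index.name = None
    if not isinstance(conditions, Mapping):
        conditions = read_conditions_yaml(conditions)
    return MiRNACountMatrix(
        values=df,
        probe_class=probe_class,
        conditions=pd.Series(dict(conditions)),
        state=state,
    )


def write_conditions_yaml(conditions: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({"samples": dict(conditions)}, sort_keys=True))
    return path


def read_conditions_yaml(path: str | Path) -> dict[str, str]:
    doc = yaml.safe_load(Path(path).read_text())
    if isinstance(doc, dict) and "samples" in doc:
        doc = doc["samples"]
    if not isinstance(doc, dict):
        raise ValueError("conditions YAML must map sample ids to condition labels")
    return {str(k): str(v) for k, v in doc.items()}


# ---------------------------------------------------------------------------
# recordings


def write_recordings_hdf5(recs: list[ElectrodeRecording], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for rec in recs:
            ds = f.create_dataset(rec.electrode_id, data=rec.samples)
            ds.attrs["sampling_rate_hz"] = rec.sampling_rate
            ds.attrs["epoch"] = rec.epoch
    return path


def read_recordings_hdf5(path: str | Path) -> list[ElectrodeRecording]:
    recs = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            ds = f[name]
            recs.append(
                ElectrodeRecording(
                    electrode_id=name,
                    sampling_rate=float(ds.attrs["sampling_rate_hz"]),
                    samples=ds[()],
                    epoch=str(ds.attrs.get("epoch", "pre")),
                )
            )
    return recs


def write_recordings_csv(recs: list[ElectrodeRecording], path: str | Path) -> Path:
    """Long format: electrode_id, epoch, sampling_rate_hz, sample_index, uv."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "electrode_id": rec.electrode_id,
                "epoch": rec.epoch,
                "sampling_rate_hz": rec.sampling_rate,
                "sample_index": np.arange(rec.samples.size),
                "uv": rec.samples,
            }
        )
        for rec in recs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_recordings_csv(path: str | Path) -> list[ElectrodeRecording]:
    df = pd.read_csv(path)
    recs = []
    for (eid, epoch, rate), sub in df.groupby(
        ["electrode_id", "epoch", "sampling_rate_hz"], sort=True
    ):
        sub = sub.sort_values("sample_index")
        recs.append(
            ElectrodeRecording(
                electrode_id=str(eid),
                sampling_rate=float(rate),
                samples=sub["uv"].to_numpy(float),
                epoch=str(epoch),
            )
        )
    return recs


# ---------------------------------------------------------------------------
# sequences / Ct tables


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_ct_csv(t: CtTable, path: str | Path) -> Path:
    path = Path(path)
    out = t.data.copy()
    out["housekeeping"] = t.housekeeping
    out.to_csv(path, index=False)
    return path


def read_ct_csv(path: str | Path, housekeeping: str | None = None) -> CtTable:
    df = pd.read_csv(path)
    if housekeeping is None:
        if "housekeeping" not in df.columns:
            raise ValueError("Ct CSV lacks a housekeeping column; pass housekeeping=")
        housekeeping = str(df["housekeeping"].iloc[0])
    return CtTable(
        data=df[["sample", "group", "target", "ct"]].copy(), housekeeping=housekeeping
    )


# ---------------------------------------------------------------------------
# truth sidecars


def truth_sidecar_path(data_path: str | Path) -> Path:
    data_path = Path(data_path)
    return data_path.with_name(data_path.stem + ".truth.json")


class _TruthEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        return super().default(o)


def write_truth_json(truth, data_path: str | Path) -> Path:
    """Write the ground-truth sidecar next to the data file."""
    path = truth_sidecar_path(data_path)
    path.write_text(json.dumps(truth, cls=_TruthEncoder, indent=2, sort_keys=True))
    return path
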