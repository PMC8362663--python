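"""File formats: recordings and epochs as TSV, images as PNG + manifest.

Every artifact directory carries a ``manifest.json`` with per-file records
(path, sha256, label, provenance, split, producing stage) so provenance
and test purity survive round-trips; hashes are verified on load.

PNGs store 8-bit quantized pixels for inspection; a lossless float TSV
twin is written alongside each image by default and preferred when
reading, so numerical pipelines are immune to quantization.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .types import Epoch, Event, GASFImage, ImageDataset, Recording, TaskLabel

__all__ = [
    "write_recording", "read_recording", "write_epochs", "read_epochs",
    "write_images", "read_images",
]

_FORMAT_VERSION = 1


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ------------------------------------------------------------- recordings

def write_recording(recording: Recording, outdir, stem: str = "recording") -> dict[str, Path]:
    """Write ``<stem>_hbo.tsv``, ``<stem>_hbr.tsv`` and ``<stem>_events.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    header = "\t".join(f"ch{c:02d}" for c in range(recording.n_channels))
    meta = (
        f"# sampling_rate_hz={recording.sampling_rate!r}"
        f" channel_side={','.join(recording.channel_side)}"
    )
    for name, data in (("hbo", recording.hbo), ("hbr", recording.hbr)):
        p = outdir / f"{stem}_{name}.tsv"
        with open(p, "w") as fh:
            fh.write(meta + "\n" + header + "\n")
            np.savetxt(fh, data.T, fmt="%.17g", delimiter="\t")
        paths[name] = p
    p = outdir / f"{stem}_events.tsv"
    with open(p, "w") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        for ev in recording.events:
            fh.write(f"{ev.onset!r}\t{ev.duration!r}\t{ev.label.name}\n")
    paths["events"] = p
    return paths


def _parse_meta(line: str, path: Path) -> tuple[float, list[str]]:
    if not line.startswith("#"):
        raise ValueError(f"{path}:1: missing metadata header line")
    fields = dict(tok.split("=", 1) for tok in line[1:].split() if "=" in tok)
    try:
        fs = float(fields["sampling_rate_hz"])
    except (KeyError, ValueError):
        raise ValueError(f"{path}:1: missing or invalid sampling_rate_hz") from None
    sides = fields.get("channel_side", "")
    return fs, (sides.split(",") if sides else [])


def read_recording(hbo_path, hbr_path, events_path) -> Recording:
    """Load a recording from its TSV triplet, validating all invariants."""
    hbo_path, hbr_path, events_path = Path(hbo_path), Path(hbr_path), Path(events_path)
    series = {}
    meta = {}
    for key, path in (("hbo", hbo_path), ("hbr", hbr_path)):
        with open(path) as fh:
            meta[key] = _parse_meta(fh.readline().rstrip("\n"), path)
            header = fh.readline().rstrip("\n").split("\t")
            try:
                data = np.loadtxt(fh, delimiter="\t", ndmin=2)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed numeric block: {exc}") from None
        if data.shape[1] != len(header):
            raise ValueError(
                f"{path}: header lists {len(header)} channels but rows have "
                f"{data.shape[1]} columns"
            )
        series[key] = data.T
    if series["hbo"].shape != series["hbr"].shape:
        raise ValueError(
            f"shape mismatch: {hbo_path} has {series['hbo'].shape}, "
            f"{hbr_path} has {series['hbr'].shape}"
        )
    if meta["hbo"][0] != meta["hbr"][0]:
        raise ValueError("hbo/hbr sampling rates disagree")

    events: list[Event] = []
    with open(events_path) as fh:
        header_line = fh.readline().rstrip("\n").split("\t")
        if header_line[:3] != ["onset_s", "duration_s", "label"]:
            raise ValueError(f"{events_path}:1: expected header onset_s/duration_s/label")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{events_path}:{lineno}: expected 3 columns")
            try:
                label = TaskLabel.from_string(parts[2])
            except ValueError as exc:
                raise ValueError(f"{events_path}:{lineno}: {exc}") from None
            events.append(Event(onset=float(parts[0]), duration=float(parts[1]), label=label))
    return Recording(
        hbo=series["hbo"], hbr=series["hbr"], sampling_rate=meta["hbo"][0],
        events=events, channel_side=meta["hbo"][1],
    )


# ------------------------------------------------------------- epochs

def write_epochs(epochs: list[Epoch], outdir, stage: str = "preprocess") -> Path:
    """Write per-epoch TSVs (HbO block then HbR block) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, ep in enumerate(epochs):
        p = outdir / f"epoch_{i:04d}.tsv"
        with open(p, "w") as fh:
            fh.write(
                f"# sampling_rate_hz={ep.sampling_rate!r} t0_offset_s={ep.t0_offset!r}"
                f" label={ep.label.name} n_channels={ep.n_channels}\n"
            )
            np.savetxt(fh, np.vstack([ep.hbo, ep.hbr]), fmt="%.17g", delimiter="\t")
        records.append({"path": p.name, "sha256": _sha256(p), "label": ep.label.name,
                        "producing_stage": stage})
    manifest = {"format_version": _FORMAT_VERSION, "kind": "epochs", "files": records}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def read_epochs(outdir) -> list[Epoch]:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    epochs = []
    for rec in manifest["files"]:
        p = outdir / rec["path"]
        if _sha256(p) != rec["sha256"]:
            raise ValueError(f"{p}: content hash mismatch against manifest")
        with open(p) as fh:
            meta = dict(tok.split("=", 1) for tok in fh.readline()[1:].split())
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        n_ch = int(meta["n_channels"])
        epochs.append(Epoch(
            hbo=data[:n_ch], hbr=data[n_ch:], t0_offset=float(meta["t0_offset_s"]),
            label=TaskLabel.from_string(meta["label"]),
            sampling_rate=float(meta["sampling_rate_hz"]),
        ))
    return epochs


# ------------------------------------------------------------- images

def write_images(dataset: ImageDataset, outdir, stage: str = "encode",
                 float_twins: bool = True) -> Path:
    """Persist images as 8-bit grayscale PNG (+ float TSV twins) with manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, img in enumerate(dataset.images):
        name = f"img_{i:04d}_{img.label.name.lower()}"
        png = outdir / f"{name}.png"
        quant = np.round(img.pixels * 255).astype(np.uint8)
        Image.fromarray(quant, mode="L").save(png)
        rec = {"path": png.name, "sha256": _sha256(png), "label": img.label.name,
               "provenance": img.provenance, "split": dataset.split,
               "producing_stage": stage}
        if float_twins:
            tsv = outdir / f"{name}.tsv"
            np.savetxt(tsv, img.pixels, fmt="%.17g", delimiter="\t")
            rec["float_path"] = tsv.name
            rec["float_sha256"] = _sha256(tsv)
        records.append(rec)
    manifest = {"format_version": _FORMAT_VERSION, "kind": "images",
                "split": dataset.split, "files": records}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def read_images(outdir) -> ImageDataset:
    """Load an image directory, preferring lossless float twins over PNGs."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    images = []
    for rec in manifest["files"]:
        if "float_path" in rec:
            p = outdir / rec["float_path"]
            if _sha256(p) != rec["float_sha256"]:
                raise ValueError(f"{p}: content hash mismatch against manifest")
            pixels = np.loadtxt(p, delimiter="\t", ndmin=2)
        else:
            p = outdir / rec["path"]
            if _sha256(p) != rec["sha256"]:
                raise ValueError(f"{p}: content hash mismatch against manifest")
            pixels = np.asarray(Image.open(p), dtype=float) / 255.0
        images.append(GASFImage(pixels=pixels, label=TaskLabel.from_string(rec["label"]),
                                provenance=rec["provenance"]))
    return ImageDataset(images, split=manifest.get("split", ""))
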