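"""Readers/writers: Bruker 1D fid/acqus, JCAMP-DX, dataset containers.

Only the 1D subsets needed by the phasing pipeline are implemented (no 2D
``ser`` files, no processed ``1r/1i`` ingestion).  The dataset container is
a NumPy ``.npz`` archive holding the complex spectra plus an embedded JSON
manifest, with the manifest also written alongside as plain JSON so the
layout is readable from any language.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .spectrum import FIDRecord, Spectrum1D
from .synth import DatasetManifest, TrainingSample, CATEGORIES
from .spectrum import PhasePair

__all__ = [
    "BrukerAcqParams",
    "RunConfig",
    "read_bruker_fid",
    "write_bruker_fixture",
    "read_jcamp",
    "write_jcamp",
    "save_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)


class RunConfig:
    """Merged pipeline configuration with lossless, order-stable JSON form.

    Bundles the generator, network, optimizer and phaser options together
    with paths and the master seed; re-serialization of a parsed config is
    byte-identical (sorted keys, canonical separators).
    """

    def __init__(self, master_seed: int = 0, synth=None, net=None, train=None,
                 phaser=None, paths: Optional[dict] = None) -> None:
        from dataclasses import asdict

        from .nn.model import NetConfig
        from .nn.train import TrainConfig
        from .phaser import PhaserOptions
        from .synth import SynthConfig

        self.master_seed = int(master_seed)
        self.synth = synth if synth is not None else SynthConfig()
        self.net = net if net is not None else NetConfig()
        self.train = train if train is not None else TrainConfig()
        self.phaser = phaser if phaser is not None else PhaserOptions()
        self.paths = dict(paths or {})
        self._asdict = asdict

    def to_json(self) -> str:
        payload = {
            "master_seed": self.master_seed,
            "synth": self._asdict(self.synth),
            "net": self._asdict(self.net),
            "train": self._asdict(self.train),
            "phaser": self._asdict(self.phaser),
            "paths": self.paths,
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"), default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        from .nn.model import NetConfig
        from .nn.train import TrainConfig
        from .phaser import PhaserOptions
        from .synth import SynthConfig

        d = json.loads(text)
        net = d["net"]
        for key in ("conv_channels", "conv_kernels", "conv_strides"):
            net[key] = tuple(net[key])
        synth = d["synth"]
        for key, val in synth.items():
            if isinstance(val, list):
                synth[key] = tuple(val)
        return cls(
            master_seed=d["master_seed"],
            synth=SynthConfig(**synth),
            net=NetConfig(**net),
            train=TrainConfig(**d["train"]),
            phaser=PhaserOptions(**d["phaser"]),
            paths=d["paths"],
        )


# ---------------------------------------------------------------------------
# Bruker directory layout: binary `fid` + key-value text `acqus`
# ---------------------------------------------------------------------------


class BrukerAcqParams:
    """Acquisition parameters parsed from an ``acqus`` file."""

    def __init__(self, td: int, sw_h: float, grpdly: float = 0.0,
                 byte_order: str = "little", data_type: str = "int32") -> None:
        if td < 4 or td % 2:
            raise ValueError("TD must be even and >= 4")
        if not sw_h > 0:
            raise ValueError("SW_h must be > 0")
        if byte_order not in ("little", "big"):
            raise ValueError("byte_order must be 'little' or 'big'")
        if data_type not in ("int32", "float64"):
            raise ValueError(f"unsupported Bruker data type {data_type!r}")
        self.td = td
        self.sw_h = sw_h
        self.grpdly = max(grpdly, 0.0)
        self.byte_order = byte_order
        self.data_type = data_type

    @property
    def np_dtype(self) -> np.dtype:
        base = {"int32": "i4", "float64": "f8"}[self.data_type]
        order = {"little": "<", "big": ">"}[self.byte_order]
        return np.dtype(order + base)


_ACQUS_RE = re.compile(r"^##\$(\w+)=\s*(.+?)\s*$")


def _parse_acqus(path: Path) -> dict:
    values = {}
    for line in path.read_text().splitlines():
        m = _ACQUS_RE.match(line)
        if m:
            values[m.group(1)] = m.group(2)
    return values


def read_bruker_fid(directory) -> FIDRecord:
    """Read a 1D Bruker dataset (``fid`` + ``acqus``) into an FIDRecord.

    Parses TD, SW_h, GRPDLY, BYTORDA and DTYPA, decodes the interleaved
    real/imaginary samples and sets ``dwell_time = 1 / SW_h``.
    """
    directory = Path(directory)
    fid_path = directory / "fid"
    acqus_path = directory / "acqus"
    if not acqus_path.is_file():
        raise FileNotFoundError(f"missing acqus file in {directory}")
    if not fid_path.is_file():
        raise FileNotFoundError(f"missing fid file in {directory}")

    raw = _parse_acqus(acqus_path)
    try:
        td = int(float(raw["TD"]))
        sw_h = float(raw["SW_h"])
    except KeyError as exc:
        raise ValueError(f"acqus is missing required key {exc}") from exc
    grpdly = float(raw.get("GRPDLY", 0.0))
    byte_order = "big" if int(float(raw.get("BYTORDA", 0))) else "little"
    dtypa = int(float(raw.get("DTYPA", 0)))
    if dtypa == 0:
        data_type = "int32"
    elif dtypa == 2:
        data_type = "float64"
    else:
        raise ValueError(f"unknown Bruker DTYPA={dtypa} (supported: 0=int32, 2=float64)")
    params = BrukerAcqParams(td, sw_h, grpdly, byte_order, data_type)

    expected = td * params.np_dtype.itemsize
    blob = fid_path.read_bytes()
    if len(blob) < expected:
        raise ValueError(
            f"fid file truncated: expected at least {expected} bytes for "
            f"TD={td}, found {len(blob)}"
        )
    data = np.frombuffer(blob[:expected], dtype=params.np_dtype).astype(float)
    samples = data[0::2] + 1j * data[1::2]
    return FIDRecord(
        samples=samples, dwell_time=1.0 / sw_h, group_delay=max(grpdly, 0.0)
    )


def write_bruker_fixture(directory, fid: FIDRecord,
                         byte_order: str = "little",
                         data_type: str = "float64") -> None:
    """Write an FIDRecord in the Bruker 1D layout (testing/fixtures only)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    td = 2 * fid.samples.size
    params = BrukerAcqParams(
        td, 1.0 / fid.dwell_time, fid.group_delay, byte_order, data_type
    )
    inter = np.empty(td, dtype=float)
    inter[0::2] = fid.samples.real
    inter[1::2] = fid.samples.imag
    if data_type == "int32":
        inter = np.round(inter)
    (directory / "fid").write_bytes(inter.astype(params.np_dtype).tobytes())
    bytorda = 1 if byte_order == "big" else 0
    dtypa = 0 if data_type == "int32" else 2
    (directory / "acqus").write_text(
        "##TITLE= synthetic fixture acqus\n"
        "##JCAMP-DX= 5.0\n"
        f"##$TD= {td}\n"
        f"##$SW_h= {1.0 / fid.dwell_time!r}\n"
        f"##$GRPDLY= {fid.group_delay!r}\n"
        f"##$BYTORDA= {bytorda}\n"
        f"##$DTYPA= {dtypa}\n"
        "##END=\n"
    )


# ---------------------------------------------------------------------------
# JCAMP-DX 5.x NTUPLES, real/imaginary pages, AFFN values
# ---------------------------------------------------------------------------

_VALUES_PER_LINE = 6


def write_jcamp(path, spec: Spectrum1D, title: str = "nmrphaser spectrum") -> None:
    """Write a complex spectrum as a JCAMP-DX NTUPLES record."""
    n = len(spec)
    sw = spec.spectral_width or float(n)
    lines = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= NMR SPECTRUM",
        "##DATA CLASS= NTUPLES",
        f"##NPOINTS= {n}",
        f"##SPECTRAL WIDTH= {sw!r}",
        "##NTUPLES= NMR SPECTRUM",
        "##VAR_NAME= FREQUENCY, SPECTRUM/REAL, SPECTRUM/IMAG",
        "##SYMBOL= X, R, I",
        "##VAR_TYPE= INDEPENDENT, DEPENDENT, DEPENDENT",
        "##VAR_FORM= AFFN, AFFN, AFFN",
        f"##VAR_DIM= {n}, {n}, {n}",
    ]
    for page, channel in (("1", spec.real), ("2", spec.imag)):
        lines.append(f"##PAGE= N={page}")
        lines.append("##DATA TABLE= (X++(Y..Y)), XYDATA")
        for start in range(0, n, _VALUES_PER_LINE):
            chunk = channel[start : start + _VALUES_PER_LINE]
            vals = " ".join(f"{v:.10g}" for v in chunk)
            lines.append(f"{start} {vals}")
    lines.append("##END NTUPLES= NMR SPECTRUM")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcamp(path) -> Spectrum1D:
    """Read a JCAMP-DX NTUPLES spectrum written by :func:`write_jcamp`.

    A file with only a real page yields a real-only spectrum with a logged
    warning; malformed label lines raise a parse error naming the line.
    """
    text = Path(path).read_text().splitlines()
    if not any(line.startswith("##TITLE=") for line in text[:5]):
        raise ValueError(f"{path}: not a JCAMP-DX file (no ##TITLE= in header)")
    npoints = None
    sw = None
    pages: List[List[float]] = []
    current: Optional[List[float]] = None
    in_table = False
    for lineno, line in enumerate(text, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            in_table = False
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: malformed label line {line!r}")
            label, _, value = line.partition("=")
            label = label[2:].strip().upper()
            value = value.strip()
            if label == "NPOINTS":
                npoints = int(value)
            elif label == "SPECTRAL WIDTH":
                sw = float(value)
            elif label == "PAGE":
                current = []
                pages.append(current)
            elif label == "DATA TABLE":
                in_table = True
            continue
        if in_table and current is not None:
            try:
                vals = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad numeric value in data table"
                ) from exc
            current.extend(vals[1:])  # first column is the X index
    if not pages or not pages[0]:
        raise ValueError(f"{path}: no data tables found")
    real = np.array(pages[0])
    if npoints is not None and real.size != npoints:
        raise ValueError(
            f"{path}: real page has {real.size} values, header says {npoints}"
        )
    if len(pages) > 1 and pages[1]:
        imag = np.array(pages[1])
        if imag.size != real.size:
            raise ValueError(f"{path}: real/imaginary page length mismatch")
    else:
        logger.warning("%s: no imaginary page, returning real-only spectrum", path)
        imag = np.zeros_like(real)
    return Spectrum1D(points=real + 1j * imag, spectral_width=sw)


# ---------------------------------------------------------------------------
# dataset container (.npz + JSON manifest)
# ---------------------------------------------------------------------------


def save_dataset(path, manifest: DatasetManifest,
                 samples: List[TrainingSample]) -> None:
    """Write spectra + manifest to one ``.npz``; manifest also as sidecar JSON.

    Layout: ``spectrum/<i>`` (complex array per sample, ordered as in the
    manifest) and ``manifest_json`` (UTF-8 bytes of the manifest).
    """
    if len(manifest.entries) != len(samples):
        raise ValueError("manifest/samples length mismatch")
    arrays = {
        f"spectrum/{i}": s.spectrum.points.astype(np.complex64)
        for i, s in enumerate(samples)
    }
    arrays["manifest_json"] = np.frombuffer(
        manifest.to_json().encode(), dtype=np.uint8
    )
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    np.savez(path, **arrays)
    path.with_name(path.name + ".manifest.json").write_text(manifest.to_json())


def load_dataset(path) -> Tuple[DatasetManifest, List[TrainingSample]]:
    """Read a dataset container back into manifest + samples."""
    path = Path(path)
    if not path.exists() and path.with_name(path.name + ".npz").exists():
        path = path.with_name(path.name + ".npz")
    with np.load(path) as data:
        manifest = DatasetManifest.from_json(bytes(data["manifest_json"]).decode())
        samples = []
        for i, entry in enumerate(manifest.entries):
            spec = Spectrum1D(points=data[f"spectrum/{i}"].astype(np.complex128))
            samples.append(
                TrainingSample(
                    spectrum=spec,
                    label=entry["label"],
                    true_phase=PhasePair(entry["true_ph0"], entry["true_ph1"]),
                    task=entry["task"],
                    provenance={"sample_id": entry["sample_id"]},
                )
            )
    return manifest, samples
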