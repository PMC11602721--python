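"""File formats, campaign configuration and decision-log plumbing.

Formats
-------
NMR spectra
    JCAMP-DX (a pragmatic subset: AFFN ``(X++(Y..Y))`` XYDATA, plus NTUPLES
    pages whose first data table holds the real part) and a documented CSV
    dialect::

        # rxntriage nmr csv v1
        # field_mhz=80.0
        ppm,intensity

    ppm axes are normalized to ascending order on read.

LC-MS runs
    mzML (centroided MS1, via pyteomics) and a documented CSV dialect::

        # rxntriage lcms csv v1
        # mode=gradient
        scan_time_min,mz,intensity

    Rows are grouped into scans by time; times must appear in strictly
    increasing order.

Campaign configuration is a YAML/JSON document validated by pydantic models;
``config_hash`` fingerprints the semantic content so decision-log records can
assert which configuration produced them.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .chemspace import (
    BuildingBlock,
    ChemspaceError,
    Formula,
    MzTable,
    Role,
    build_lookup_table,
)
from .msproc import LcmsRun, MassSpectrum
from .nmrproc import NmrSpectrum

__all__ = [
    "IoError",
    "read_nmr",
    "write_nmr",
    "read_lcms",
    "write_lcms",
    "CampaignConfig",
    "load_config",
    "config_hash",
    "blocks_from_config",
    "lookup_table_from_config",
    "evidence_digest",
    "append_jsonl",
    "read_jsonl",
    "write_bundle",
    "read_bundle",
]


class IoError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# NMR readers/writers
# ---------------------------------------------------------------------------


def _nmr_from_arrays(ppm, intensity, field_mhz) -> NmrSpectrum:
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ppm.size >= 2 and ppm[0] > ppm[-1]:  # descending axis convention
        ppm, intensity = ppm[::-1].copy(), intensity[::-1].copy()
    return NmrSpectrum(ppm, intensity, field_mhz=field_mhz)


def read_nmr(path, dialect: str | None = None, field_mhz: float = 80.0) -> NmrSpectrum:
    """Read a 1H spectrum from JCAMP-DX or the CSV dialect.

    ``dialect`` is inferred from the extension (.jdx/.dx -> jcamp, .csv ->
    csv) when not given. Malformed axes raise :class:`IoError` with context.
    """
    path = Path(path)
    if dialect is None:
        dialect = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"
    if dialect == "jcamp":
        return _read_jcamp(path, field_mhz)
    if dialect == "csv":
        return _read_nmr_csv(path, field_mhz)
    raise IoError(f"unknown NMR dialect {dialect!r}; use jcamp|csv")


def _read_nmr_csv(path, field_mhz: float) -> NmrSpectrum:
    ppm, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "field_mhz=" in line:
                    field_mhz = float(line.split("field_mhz=")[1])
                continue
            if line.lower().startswith("ppm"):
                continue
            parts = line.split(",")
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise IoError(f"{path}:{lineno}: malformed row {line!r}") from exc
    if len(ppm) < 2:
        raise IoError(f"{path}: no spectral data found")
    return _nmr_from_arrays(ppm, inten, field_mhz)


def write_nmr(spec: NmrSpectrum, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"
    if dialect == "csv":
        with open(path, "w") as fh:
            fh.write("# rxntriage nmr csv v1\n")
            fh.write(f"# field_mhz={spec.field_mhz}\n")
            fh.write("ppm,intensity\n")
            for x, y in zip(spec.ppm, spec.intensity):
                fh.write(f"{x:.9g},{y:.9g}\n")
    elif dialect == "jcamp":
        _write_jcamp(spec, path)
    else:
        raise IoError(f"unknown NMR dialect {dialect!r}")


def _write_jcamp(spec: NmrSpectrum, path) -> None:
    n = spec.ppm.size
    step = (spec.ppm[-1] - spec.ppm[0]) / (n - 1)
    with open(path, "w") as fh:
        fh.write("##TITLE=rxntriage spectrum\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write("##XUNITS=PPM\n##YUNITS=ARBITRARY UNITS\n")
        fh.write(f"##.OBSERVE FREQUENCY={spec.field_mhz}\n")
        fh.write(f"##FIRSTX={spec.ppm[0]:.9g}\n##LASTX={spec.ppm[-1]:.9g}\n")
        fh.write(f"##DELTAX={step:.9g}\n##NPOINTS={n}\n")
        fh.write("##XFACTOR=1\n##YFACTOR=1\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        per_line = 6
        for i in range(0, n, per_line):
            ys = " ".join(f"{y:.9g}" for y in spec.intensity[i : i + per_line])
            fh.write(f"{spec.ppm[i]:.9g} {ys}\n")
        fh.write("##END=\n")


def _read_jcamp(path, default_field: float) -> NmrSpectrum:
    """Minimal JCAMP-DX reader: AFFN (X++(Y..Y)) data, NTUPLES first real page.

    Unknown label records are skipped. SQZ/DIF/DUP compression is not
    supported and raises.
    """
    records: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    seen_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                in_data = False
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                val = val.strip()
                if key in ("XYDATA", "DATA TABLE"):
                    # only the first data table is read (the real part)
                    if not seen_table:
                        in_data = True
                        seen_table = True
                        records[key] = val
                else:
                    records.setdefault(key, val)
            elif in_data and line.strip():
                data_lines.append(line.strip())
    if not data_lines:
        raise IoError(f"{path}: no XYDATA/DATA TABLE block found")
    try:
        npoints = int(float(records.get("NPOINTS", records.get("VAR_DIM", "0")).split(",")[0]))
        firstx = float(records["FIRSTX"].split(",")[0])
        lastx = float(records["LASTX"].split(",")[0])
        xfactor = float(records.get("XFACTOR", "1").split(",")[0] or 1)
        yfactor = float(records.get("YFACTOR", "1").split(",")[0] or 1)
    except (KeyError, ValueError) as exc:
        raise IoError(f"{path}: missing or malformed axis records ({exc})") from exc
    field = default_field
    for key in (".OBSERVE FREQUENCY", "OBSERVE FREQUENCY", ".SF"):
        if key in records:
            try:
                field = float(records[key].split()[0])
            except ValueError:
                pass
            break
    ys: list[float] = []
    for ln in data_lines:
        toks = ln.replace(",", " ").split()
        for tok in toks[1:]:  # first token is the line's X value
            try:
                ys.append(float(tok))
            except ValueError:
                raise IoError(
                    f"{path}: unsupported data token {tok!r} "
                    "(SQZ/DIF compression is not supported)"
                ) from None
    if npoints and len(ys) != npoints:
        if len(ys) < 2:
            raise IoError(f"{path}: expected {npoints} points, found {len(ys)}")
    n = len(ys)
    x = np.linspace(firstx * xfactor, lastx * xfactor, n)
    y = yfactor * np.asarray(ys)
    return _nmr_from_arrays(x, y, field)


# ---------------------------------------------------------------------------
# LC-MS readers/writers
# ---------------------------------------------------------------------------


def read_lcms(path, dialect: str | None = None, mode: str = "gradient") -> LcmsRun:
    """Read an LC-MS run from mzML or the CSV dialect."""
    path = Path(path)
    if dialect is None:
        dialect = "mzml" if path.suffix.lower() == ".mzml" else "csv"
    if dialect == "mzml":
        return _read_mzml(path, mode)
    if dialect == "csv":
        return _read_lcms_csv(path, mode)
    raise IoError(f"unknown LC-MS dialect {dialect!r}; use mzml|csv")


def _read_lcms_csv(path, mode: str) -> LcmsRun:
    times: list[float] = []
    scans: list[tuple[list[float], list[float]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "mode=" in line:
                    mode = line.split("mode=")[1].strip()
                continue
            if line.lower().startswith("scan_time"):
                continue
            parts = line.split(",")
            try:
                t = float(parts[0])
                empty = len(parts) < 3 or parts[1].strip() == ""
                if not empty:
                    mz, inten = float(parts[1]), float(parts[2])
            except (IndexError, ValueError) as exc:
                raise IoError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if not times or t > times[-1]:
                times.append(t)
                scans.append(([], []))
            elif t < times[-1]:
                raise IoError(f"{path}:{lineno}: scan times out of order ({t} after {times[-1]})")
            if not empty:
                scans[-1][0].append(mz)
                scans[-1][1].append(inten)
    if not times:
        raise IoError(f"{path}: no scan data found")
    specs = []
    for mzs, ints in scans:
        order = np.argsort(mzs)
        specs.append(MassSpectrum(np.asarray(mzs)[order], np.asarray(ints)[order]))
    return LcmsRun(mode=mode, times=np.asarray(times), scans=specs)


def _read_mzml(path, mode: str) -> LcmsRun:
    from pyteomics import mzml as _mzml

    times, specs = [], []
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level", 1) != 1:
                continue
            t = scan["scanList"]["scan"][0]["scan start time"]
            t_min = float(t)
            if getattr(t, "unit_info", "minute") in ("second", "seconds"):
                t_min /= 60.0
            mz = np.asarray(scan["m/z array"], dtype=float)
            inten = np.asarray(scan["intensity array"], dtype=float)
            order = np.argsort(mz)
            times.append(t_min)
            specs.append(MassSpectrum(mz[order], inten[order]))
    if not times:
        raise IoError(f"{path}: no MS1 scans found")
    order = np.argsort(times)
    return LcmsRun(
        mode=mode,
        times=np.asarray(times)[order],
        scans=[specs[i] for i in order],
    )


def write_lcms(run: LcmsRun, path) -> None:
    """Write a run in the CSV dialect (the portable text format)."""
    with open(path, "w") as fh:
        fh.write("# rxntriage lcms csv v1\n")
        fh.write(f"# mode={run.mode}\n")
        fh.write("scan_time_min,mz,intensity\n")
        for t, scan in zip(run.times, run.scans):
            if scan.mz.size == 0:
                fh.write(f"{t:.9g},,\n")  # empty-scan placeholder keeps the scan grid
                continue
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{t:.9g},{mz:.9g},{inten:.9g}\n")


# ---------------------------------------------------------------------------
# Campaign configuration
# ---------------------------------------------------------------------------


class BlockConfig(BaseModel):
    id: str
    role: str
    formula: str
    topicity: int = 0
    charge: int = 0

    @field_validator("role")
    @classmethod
    def _known_role(cls, v):
        Role(v)
        return v


class AssemblyConfig(BaseModel):
    counterion: str  # block id; no default chemical identity
    max_metals: dict[str, int] = Field(default_factory=dict)
    default_max_metals: int = 10
    include_mononuclear: bool = True
    mz_tolerance: float = 0.5


class StageConfig(BaseModel):
    stage: str
    nmr_mode: str = "dtw"
    ms_mode: str = "targeted"
    thresholds: dict[str, float | str] = Field(default_factory=dict)
    combine: str = "AND"


class CampaignConfig(BaseModel):
    """Schema-validated campaign definition."""

    kind: str = "divergent"
    building_blocks: list[BlockConfig] = Field(default_factory=list)
    assembly: Optional[AssemblyConfig] = None
    stages: list[StageConfig] = Field(default_factory=list)
    replicate_count: int = 6
    diversifications: list[str] = Field(default_factory=list)
    guests: list[str] = Field(default_factory=list)
    masked_regions: list[tuple[float, float]] = Field(default_factory=list)

    def block_map(self) -> dict[str, BuildingBlock]:
        return blocks_from_config(self)


def load_config(path) -> CampaignConfig:
    """Load and validate a YAML/JSON campaign config.

    Raises :class:`IoError` listing the offending keys on schema violations
    or dangling cross-references.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        cfg = CampaignConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join("/".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise IoError(f"invalid campaign config {path}: offending keys: {keys}") from exc
    ids = [b.id for b in cfg.building_blocks]
    if len(set(ids)) != len(ids):
        raise IoError(f"duplicate building-block ids in {path}")
    if cfg.assembly is not None:
        known = set(ids)
        if cfg.assembly.counterion not in known:
            raise IoError(
                f"assembly.counterion {cfg.assembly.counterion!r} does not "
                f"reference a defined building block"
            )
        for mid in cfg.assembly.max_metals:
            if mid not in known:
                raise IoError(f"assembly.max_metals references unknown block {mid!r}")
    return cfg


def blocks_from_config(cfg: CampaignConfig) -> dict[str, BuildingBlock]:
    out = {}
    for b in cfg.building_blocks:
        try:
            out[b.id] = BuildingBlock(
                b.id, Role(b.role), Formula(b.formula), topicity=b.topicity, charge=b.charge
            )
        except ChemspaceError as exc:
            raise IoError(f"building block {b.id!r}: {exc}") from exc
    return out


def lookup_table_from_config(cfg: CampaignConfig) -> MzTable:
    if cfg.assembly is None:
        raise IoError("config has no assembly section")
    blocks = blocks_from_config(cfg)
    pyridines = [b for b in blocks.values() if b.role is Role.CARBONYL_PYRIDINE]
    amines = [b for b in blocks.values() if b.role is Role.POLYTOPIC_AMINE]
    metals = [b for b in blocks.values() if b.role is Role.METAL_ION]
    max_metals = {
        m.id: cfg.assembly.max_metals.get(m.id, cfg.assembly.default_max_metals)
        for m in metals
    }
    return build_lookup_table(
        pyridines,
        amines,
        metals,
        blocks[cfg.assembly.counterion],
        max_metals=max_metals,
        include_mononuclear=cfg.assembly.include_mononuclear,
        tolerance=cfg.assembly.mz_tolerance,
    )


def config_hash(cfg: CampaignConfig) -> str:
    """sha256 over the canonical JSON dump; changes iff semantics change."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Decision log
# ---------------------------------------------------------------------------


def evidence_digest(evidence) -> str:
    """Stable fingerprint of an evidence payload for the decision log."""
    payload = json.dumps(evidence, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def append_jsonl(path, record: Mapping) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(dict(record), sort_keys=True) + "\n")


def read_jsonl(path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


# ---------------------------------------------------------------------------
# Bundle persistence (synthetic campaigns as directories of text files)
# ---------------------------------------------------------------------------


def write_bundle(bundle, outdir) -> Path:
    """Write a synthetic campaign bundle to a directory of CSV + JSON files."""
    from . import synthgen

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"truth": _truth_dict(bundle.truth)}

    def save_nmr(spec, name):
        write_nmr(spec, outdir / name)
        return name

    def save_lcms(run, name):
        write_lcms(run, outdir / name)
        return name

    if isinstance(bundle, synthgen.SupramolecularBundle):
        manifest["kind"] = "supramolecular"
        manifest["combos"] = bundle.combos
        manifest["guests"] = bundle.guests
        manifest["replicate_count"] = bundle.replicate_count
        bundle.table.to_json(outdir / "table.json")
        manifest["table"] = "table.json"
        manifest["sm_nmr"] = {
            c: [save_nmr(s, f"sm_{c}_{k}.csv") for k, s in enumerate(specs)]
            for c, specs in bundle.sm_nmr.items()
        }
        manifest["screen_nmr"] = {
            c: save_nmr(s, f"screen_{c}.csv") for c, s in bundle.screen_nmr.items()
        }
        manifest["screen_ms"] = {
            c: save_lcms(r, f"screenms_{c}.csv") for c, r in bundle.screen_ms.items()
        }
        manifest["replicate_nmr"] = {
            c: [save_nmr(s, f"rep_{c}_{k}.csv") for k, s in enumerate(specs)]
            for c, specs in bundle.replicate_nmr.items()
        }
        manifest["replicate_ms"] = {
            c: [save_lcms(r, f"repms_{c}_{k}.csv") for k, r in enumerate(runs)]
            for c, runs in bundle.replicate_ms.items()
        }
        manifest["host_nmr"] = {
            c: save_nmr(s, f"host_{c}.csv") for c, s in bundle.host_nmr.items()
        }
        manifest["guest_nmr"] = {
            f"{c}|{g}": save_nmr(s, f"guest_{c}_{g}.csv")
            for (c, g), s in bundle.guest_nmr.items()
        }
    elif isinstance(bundle, synthgen.DivergentBundle):
        manifest["kind"] = "divergent"
        manifest["reactions"] = bundle.reactions
        manifest["diversifications"] = bundle.diversifications
        manifest["expected_mz"] = bundle.expected_mz
        manifest["diversify_expected"] = {
            f"{r}|{d}": v for (r, d), v in bundle.diversify_expected.items()
        }
        manifest["sm_nmr"] = {
            r: [save_nmr(s, f"sm_{r}_{k}.csv") for k, s in enumerate(specs)]
            for r, specs in bundle.sm_nmr.items()
        }
        manifest["screen_nmr"] = {
            r: save_nmr(s, f"screen_{r}.csv") for r, s in bundle.screen_nmr.items()
        }
        manifest["screen_lcms"] = {
            r: save_lcms(x, f"screenlc_{r}.csv") for r, x in bundle.screen_lcms.items()
        }
        manifest["scaleup_nmr"] = {
            r: save_nmr(s, f"scaleup_{r}.csv") for r, s in bundle.scaleup_nmr.items()
        }
        manifest["scaleup_lcms"] = {
            r: save_lcms(x, f"scaleuplc_{r}.csv") for r, x in bundle.scaleup_lcms.items()
        }
        manifest["diversify_lcms"] = {
            f"{r}|{d}": save_lcms(x, f"divlc_{r}_{d.replace(':', '-')}.csv")
            for (r, d), x in bundle.diversify_lcms.items()
        }
    else:
        raise IoError(f"unknown bundle type {type(bundle).__name__}")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def _truth_dict(truth) -> dict:
    return {
        "true_reactions": truth.true_reactions,
        "product_labels": truth.product_labels,
        "assembly_stoichiometry": {k: list(v) for k, v in truth.assembly_stoichiometry.items()},
        "binding": {f"{h}|{g}": v for (h, g), v in truth.binding.items()},
    }


def read_bundle(indir):
    """Reload a bundle directory written by :func:`write_bundle`."""
    from . import synthgen

    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        man = json.load(fh)
    t = man["truth"]
    truth = synthgen.CampaignTruth(
        true_reactions=t["true_reactions"],
        product_labels=t.get("product_labels", {}),
        assembly_stoichiometry={
            k: tuple(v) for k, v in t.get("assembly_stoichiometry", {}).items()
        },
        binding={
            tuple(k.split("|")): v for k, v in t.get("binding", {}).items()
        },
    )

    def nmr(name):
        return read_nmr(indir / name)

    def lcms(name, mode):
        return read_lcms(indir / name, mode=mode)

    if man["kind"] == "supramolecular":
        return synthgen.SupramolecularBundle(
            combos=man["combos"],
            blocks=synthgen.default_supramolecular_blocks(),
            table=MzTable.from_json(indir / man["table"]),
            sm_nmr={c: [nmr(n) for n in names] for c, names in man["sm_nmr"].items()},
            screen_nmr={c: nmr(n) for c, n in man["screen_nmr"].items()},
            screen_ms={c: lcms(n, "direct_injection") for c, n in man["screen_ms"].items()},
            replicate_nmr={
                c: [nmr(n) for n in names] for c, names in man["replicate_nmr"].items()
            },
            replicate_ms={
                c: [lcms(n, "direct_injection") for n in names]
                for c, names in man["replicate_ms"].items()
            },
            host_nmr={c: nmr(n) for c, n in man["host_nmr"].items()},
            guest_nmr={
                tuple(k.split("|")): nmr(n) for k, n in man["guest_nmr"].items()
            },
            guests=man["guests"],
            replicate_count=man["replicate_count"],
            truth=truth,
        )
    if man["kind"] == "divergent":
        return synthgen.DivergentBundle(
            reactions=man["reactions"],
            blocks=synthgen.default_divergent_blocks(),
            sm_nmr={r: [nmr(n) for n in names] for r, names in man["sm_nmr"].items()},
            screen_nmr={r: nmr(n) for r, n in man["screen_nmr"].items()},
            screen_lcms={r: lcms(n, "gradient") for r, n in man["screen_lcms"].items()},
            expected_mz={
                r: [(lbl, float(mz)) for lbl, mz in v] for r, v in man["expected_mz"].items()
            },
            scaleup_nmr={r: nmr(n) for r, n in man["scaleup_nmr"].items()},
            scaleup_lcms={r: lcms(n, "gradient") for r, n in man["scaleup_lcms"].items()},
            diversifications=man["diversifications"],
            diversify_lcms={
                tuple(k.split("|")): lcms(n, "gradient")
                for k, n in man["diversify_lcms"].items()
            },
            diversify_expected={
                tuple(k.split("|")): [(lbl, float(mz)) for lbl, mz in v]
                for k, v in man["diversify_expected"].items()
            },
            truth=truth,
        )
    raise IoError(f"unknown bundle kind {man['kind']!r}")
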