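"""Run configuration: TOML loading, validation, presets and assembly.

Configurations are TOML files whose numeric keys carry an explicit unit
suffix (``_mm``, ``_um``, ``_us``, ``_ms``, ``_hz``, ``_rad``, ``_kpa`` ...)
and are converted to SI on load.  Unknown keys are errors, not warnings.
A packaged preset named ``prostate_table3`` reproduces the transluminal
prostate scenario (20 x 40 mm domain outside a 3.25 mm lumen, 150 um grid,
20 us step, 42 ms run, 1 ms memory time, 60-node PML, 700 Hz / 0.3 rad
Gaussian monocycle, 32 receivers, 4 mm tumour at (16, 36) mm).
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .grid import MaterialMap, add_circular_inclusion, build_grid
from .rheology import KVFDMaterial, MATERIALS, get_material
from .solver import ReceiverArray, SourceSpec, TorsionalSolver, gaussian_monocycle, tone_burst

__all__ = ["Inclusion", "RunConfig", "load_config", "loads_config",
           "save_config", "preset_path", "build_simulation"]

_UNIT_FACTORS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6,
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "hz": 1.0, "khz": 1e3,
    "rad": 1.0,
    "pa": 1.0, "kpa": 1e3,
    "kgm3": 1.0,
    "pasa": 1.0,
}


@dataclass(frozen=True)
class Inclusion:
    """A circular region of different material inside the tissue domain."""

    center_r: float
    center_z: float
    diameter: float
    material: KVFDMaterial


@dataclass
class RunConfig:
    """Fully validated run description in SI units."""

    # geometry
    rd: float
    zd: float
    ru: float
    # discretisation
    dr: float
    dz: float
    dt: float
    t_total: float
    t_memory: float
    n_pml: int
    # materials
    background: KVFDMaterial
    inclusions: list[Inclusion] = field(default_factory=list)
    # probe
    emitter_z: float = 1e-3
    emitter_length: float = 2e-3
    frequency: float = 700.0
    amplitude: float = 0.3
    waveform: str = "gaussian_monocycle"
    n_receivers: int = 32
    receiver_spacing: float = 0.8e-3
    receiver_length: float = 0.5e-3
    receiver_start: float = 3.0e-3
    # outputs
    trace_csv: str | None = None
    snapshot_times: list[float] = field(default_factory=list)
    log_level: str = "info"

    def validate(self) -> "RunConfig":
        pos = {
            "rd": self.rd, "zd": self.zd, "ru": self.ru, "dr": self.dr,
            "dz": self.dz, "dt": self.dt, "t_total": self.t_total,
            "emitter_length": self.emitter_length, "frequency": self.frequency,
            "receiver_spacing": self.receiver_spacing,
        }
        for key, val in pos.items():
            if not (val > 0) or not math.isfinite(val):
                raise ValueError(f"config value {key} must be positive, got {val}")
        if self.t_memory < 0:
            raise ValueError("t_memory must be >= 0")
        if self.t_memory > self.t_total:
            raise ValueError(
                f"t_memory ({self.t_memory}) must not exceed t_total ({self.t_total})"
            )
        if self.n_pml < 0 or self.n_receivers < 0:
            raise ValueError("n_pml and n_receivers must be >= 0")
        if self.waveform not in ("gaussian_monocycle", "tone_burst"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        emitter_hi = self.emitter_z + self.emitter_length / 2
        if self.emitter_z - self.emitter_length / 2 < -1e-12 or emitter_hi > self.zd:
            raise ValueError("emitter does not fit on the lumen wall")
        if self.n_receivers:
            last = self.receiver_start + (self.n_receivers - 1) * self.receiver_spacing
            if self.receiver_start - self.receiver_length / 2 < emitter_hi:
                raise ValueError("first receiver overlaps the emitter")
            if last + self.receiver_length / 2 > self.zd:
                raise ValueError("receiver array does not fit on the lumen wall")
        return self


# ---------------------------------------------------------------------------
# schema-driven parsing
# ---------------------------------------------------------------------------

# (section, key) -> RunConfig attribute; key unit suffix handled generically
_SCHEMA = {
    ("geometry", "rd"): "rd",
    ("geometry", "zd"): "zd",
    ("geometry", "ru"): "ru",
    ("discretisation", "dr"): "dr",
    ("discretisation", "dz"): "dz",
    ("discretisation", "dt"): "dt",
    ("discretisation", "t_total"): "t_total",
    ("discretisation", "t_memory"): "t_memory",
    ("discretisation", "n_pml"): "n_pml",
    ("probe", "emitter_z"): "emitter_z",
    ("probe", "emitter_length"): "emitter_length",
    ("probe", "frequency"): "frequency",
    ("probe", "amplitude"): "amplitude",
    ("probe", "waveform"): "waveform",
    ("probe", "n_receivers"): "n_receivers",
    ("probe", "receiver_spacing"): "receiver_spacing",
    ("probe", "receiver_length"): "receiver_length",
    ("probe", "receiver_start"): "receiver_start",
    ("outputs", "trace_csv"): "trace_csv",
    ("outputs", "log_level"): "log_level",
}
_NO_UNIT_KEYS = {"n_pml", "waveform", "n_receivers", "trace_csv", "log_level",
                 "background", "material", "shape", "alpha"}
_MATERIAL_KEYS = {"mu", "eta", "alpha", "rho"}
_INCLUSION_KEYS = {"shape", "center_r", "center_z", "diameter", "material"}


def _split_unit(key: str):
    """Split a trailing unit suffix off a config key name."""
    base, _, suffix = key.rpartition("_")
    if base and suffix in _UNIT_FACTORS:
        return base, _UNIT_FACTORS[suffix]
    return key, None


def _converted_items(section: str, table: dict) -> dict:
    out = {}
    for key, value in table.items():
        base, factor = _split_unit(key)
        if factor is None:
            if base not in _NO_UNIT_KEYS:
                raise ValueError(
                    f"config key [{section}] {key!r}: unknown key or missing "
                    "unit suffix"
                )
            out[base] = value
        else:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"config key [{section}] {key!r} must be numeric")
            out[base] = float(value) * factor
    return out


def _parse_material(name: str, table: dict) -> KVFDMaterial:
    vals = _converted_items(f"materials.custom.{name}", table)
    unknown = set(vals) - _MATERIAL_KEYS
    if unknown:
        raise ValueError(f"unknown material keys for {name!r}: {sorted(unknown)}")
    missing = _MATERIAL_KEYS - set(vals)
    if missing:
        raise ValueError(f"material {name!r} missing keys: {sorted(missing)}")
    return KVFDMaterial(
        density=vals["rho"], shear_elastic=vals["mu"],
        shear_viscous=vals["eta"], fractional_order=vals["alpha"], name=name,
    )


def loads_config(text: str) -> RunConfig:
    """Parse and validate a TOML configuration string."""
    raw = tomllib.loads(text)
    known_sections = {"geometry", "discretisation", "materials", "probe", "outputs"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    fields: dict = {}
    for section in ("geometry", "discretisation", "probe", "outputs"):
        table = dict(raw.get(section, {}))
        if section == "outputs":
            snap = table.pop("snapshot_times_ms", None)
            if snap is not None:
                fields["snapshot_times"] = [float(t) * 1e-3 for t in snap]
        for base, value in _converted_items(section, table).items():
            if (section, base) not in _SCHEMA:
                raise ValueError(f"unknown config key [{section}] {base!r}")
            fields[_SCHEMA[(section, base)]] = value

    mats = dict(raw.get("materials", {}))
    custom = {
        name: _parse_material(name, tbl)
        for name, tbl in dict(mats.pop("custom", {})).items()
    }

    def _resolve(name: str) -> KVFDMaterial:
        if name in custom:
            return custom[name]
        return get_material(name)

    background = mats.pop("background", None)
    if background is None:
        raise ValueError("config key [materials] background is required")
    fields["background"] = _resolve(background)

    inclusions = []
    for k, tbl in enumerate(mats.pop("inclusions", [])):
        vals = _converted_items(f"materials.inclusions[{k}]", dict(tbl))
        unknown = set(vals) - _INCLUSION_KEYS
        if unknown:
            raise ValueError(f"unknown inclusion keys: {sorted(unknown)}")
        if vals.get("shape", "circle") != "circle":
            raise ValueError(f"unsupported inclusion shape {vals.get('shape')!r}")
        inclusions.append(
            Inclusion(
                center_r=vals["center_r"], center_z=vals["center_z"],
                diameter=vals["diameter"], material=_resolve(vals["material"]),
            )
        )
    fields["inclusions"] = inclusions
    if mats:
        raise ValueError(f"unknown config keys in [materials]: {sorted(mats)}")

    try:
        cfg = RunConfig(**fields)
    except TypeError as err:
        raise ValueError(f"incomplete configuration: {err}") from None
    cfg.n_pml = int(cfg.n_pml)
    cfg.n_receivers = int(cfg.n_receivers)
    return cfg.validate()


def load_config(path) -> RunConfig:
    """Load and validate a TOML configuration file or packaged preset name."""
    p = Path(path)
    if not p.exists():
        candidate = preset_path(str(path))
        if candidate is not None:
            p = candidate
        else:
            raise FileNotFoundError(f"no such config file or preset: {path}")
    return loads_config(p.read_text())


def preset_path(name: str) -> Path | None:
    """Path of a packaged preset config (without the .toml suffix), if any."""
    base = resources.files("kvfdwave") / "presets" / f"{name}.toml"
    try:
        return Path(str(base)) if base.is_file() else None
    except (OSError, ValueError):
        return None


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig back to TOML.

    Values are emitted in base SI units (``_m``, ``_s`` suffixes, unit
    factor exactly 1), so a save/load round-trip is bit-exact.
    """
    lines = [
        "[geometry]",
        f"rd_m = {cfg.rd!r}",
        f"zd_m = {cfg.zd!r}",
        f"ru_m = {cfg.ru!r}",
        "",
        "[discretisation]",
        f"dr_m = {cfg.dr!r}",
        f"dz_m = {cfg.dz!r}",
        f"dt_s = {cfg.dt!r}",
        f"t_total_s = {cfg.t_total!r}",
        f"t_memory_s = {cfg.t_memory!r}",
        f"n_pml = {cfg.n_pml}",
        "",
        "[materials]",
        f'background = "{cfg.background.name}"',
    ]
    customs = {m.name: m for m in [cfg.background] + [i.material for i in cfg.inclusions]
               if m.name not in MATERIALS}
    for name, m in customs.items():
        lines += [
            "",
            f"[materials.custom.{name}]",
            f"mu_pa = {m.shear_elastic!r}",
            f"eta_pasa = {m.shear_viscous!r}",
            f"alpha = {m.fractional_order!r}",
            f"rho_kgm3 = {m.density!r}",
        ]
    for inc in cfg.inclusions:
        lines += [
            "",
            "[[materials.inclusions]]",
            'shape = "circle"',
            f"center_r_m = {inc.center_r!r}",
            f"center_z_m = {inc.center_z!r}",
            f"diameter_m = {inc.diameter!r}",
            f'material = "{inc.material.name}"',
        ]
    lines += [
        "",
        "[probe]",
        f"emitter_z_m = {cfg.emitter_z!r}",
        f"emitter_length_m = {cfg.emitter_length!r}",
        f"frequency_hz = {cfg.frequency!r}",
        f"amplitude_rad = {cfg.amplitude!r}",
        f'waveform = "{cfg.waveform}"',
        f"n_receivers = {cfg.n_receivers}",
        f"receiver_spacing_m = {cfg.receiver_spacing!r}",
        f"receiver_length_m = {cfg.receiver_length!r}",
        f"receiver_start_m = {cfg.receiver_start!r}",
        "",
        "[outputs]",
        f'log_level = "{cfg.log_level}"',
    ]
    if cfg.trace_csv:
        lines.append(f'trace_csv = "{cfg.trace_csv}"')
    if cfg.snapshot_times:
        snap = ", ".join(repr(t * 1e3) for t in cfg.snapshot_times)
        lines.append(f"snapshot_times_ms = [{snap}]")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_simulation(cfg: RunConfig, include_inclusions: bool = True):
    """Assemble (solver, source, receivers, n_steps) from a RunConfig."""
    grid = build_grid(cfg.rd, cfg.zd, cfg.ru, cfg.dr, cfg.dz, cfg.n_pml)
    mat_map = MaterialMap.homogeneous(grid, cfg.background)
    if include_inclusions:
        for inc in cfg.inclusions:
            mat_map = add_circular_inclusion(
                mat_map, (inc.center_r, inc.center_z), inc.diameter, inc.material
            )
    from .grid import build_pml

    pml = build_pml(grid, cfg.background.elastic_velocity,
                    alpha_max=np.pi * cfg.frequency)
    solver = TorsionalSolver(grid, mat_map, dt=cfg.dt, t_memory=cfg.t_memory,
                             pml=pml)
    n_steps = int(round(cfg.t_total / cfg.dt))
    times = cfg.dt * np.arange(n_steps + 1)
    wave = gaussian_monocycle if cfg.waveform == "gaussian_monocycle" else tone_burst
    samples = wave(cfg.frequency, cfg.amplitude, cfg.ru, times)
    source = SourceSpec(z_center=cfg.emitter_z, length=cfg.emitter_length,
                        samples=samples)
    receivers = None
    if cfg.n_receivers:
        receivers = ReceiverArray.uniform(
            cfg.n_receivers, cfg.receiver_start, cfg.receiver_spacing,
            cfg.receiver_length,
        )
    return solver, source, receivers, n_steps
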