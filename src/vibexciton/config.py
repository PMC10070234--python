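"""Run configuration: schema-validated settings, presets, and builders.

Configs are YAML (JSON is a YAML subset) with sections mirroring the model:
[states], [modes], [vc_mode], [bath], [disorder], [coupling], [geometry],
[grid].  Field names carry units (``*_cm1``, ``*_angstrom``, ``*_k``, ...)
and unknown keys are rejected.  Two presets ship:

* ``ether``  -- an isolated chlorophyll-a monomer in diethyl ether
  (inhomogeneous FWHM 240 / 720 cm^-1 for Qy / Qx);
* ``wscp``   -- the strongly coupled chlorophyll-a homodimer of the
  water-soluble chlorophyll-binding protein (FWHM 170 / 340 cm^-1).

The Soret transitions use FWHM 1800 cm^-1 in both presets.  The disorder
widths are also available standalone as ``DISORDER_PRESETS['ether-like']``
and ``DISORDER_PRESETS['wscp']`` (the dimer is sometimes analysed with the
broader ether-like widths).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import geometry as geometry_mod
from .bath import SpectralDensity
from .dimer import (
    CouplingMatrix,
    ExcitonSystem,
    assemble_dimer,
    monomer_system,
    scaled_couplings,
)
from .modes import (
    BX, BY, QX, QY,
    ElectronicState,
    ModeCatalog,
    MonomerParams,
    VibrationalMode,
    VibronicCouplingMode,
    chla_mode_catalog,
)
from .monomer import assemble_monomer
from .spectra import DisorderModel, SpectrumEngine, TimeGrid
from .units import wavenumber_to_nm  # noqa: F401  (re-exported convenience)

__all__ = [
    "RunConfig",
    "DISORDER_PRESETS",
    "preset_config",
    "load_config",
    "dump_resolved",
    "apply_variant",
    "build_mode_catalog",
    "build_monomer_params",
    "build_geometry",
    "build_couplings",
    "build_system",
    "build_disorder",
    "build_engine",
]


DISORDER_PRESETS: dict[str, dict[str, float]] = {
    "ether-like": {QY: 240.0, QX: 720.0, BY: 1800.0, BX: 1800.0},
    "wscp": {QY: 170.0, QX: 340.0, BY: 1800.0, BX: 1800.0},
}


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class StatesConfig(_Section):
    include_qx: bool = True
    include_b: bool = True
    delta_qx_cm1: float = Field(1640.0, gt=0)
    f_qx: float = Field(0.1, ge=0)
    delta_by_cm1: float = Field(7570.0, gt=0)
    f_by: float = Field(2.52, ge=0)
    delta_bx_cm1: float = Field(8740.0, gt=0)
    f_bx: float = Field(2.43, ge=0)
    qy_energy_absolute_cm1: float = Field(0.0, ge=0)


class ModeEntry(_Section):
    frequency_cm1: float = Field(gt=0)
    huang_rhys_qy: float = Field(ge=0)
    huang_rhys_qx: Optional[float] = Field(None, ge=0)


class ModesConfig(_Section):
    catalog: Literal["chla", "custom", "none"] = "chla"
    qx_displacement_factor: float = Field(3.0, gt=0)
    custom: tuple[ModeEntry, ...] = ()


class VcModeConfig(_Section):
    frequency_cm1: float = Field(1500.0, gt=0)
    coupling_cm1: float = Field(750.0, ge=0)
    max_quanta: int = Field(4, ge=0)


class BathConfig(_Section):
    s1: float = Field(0.402, ge=0)
    s2: float = Field(0.398, ge=0)
    omega1_cm1: float = Field(0.557, gt=0)
    omega2_cm1: float = Field(1.94, gt=0)
    rescale_total_huang_rhys: Optional[float] = Field(None, gt=0)
    temperature_k: float = Field(300.0, gt=0)


class DisorderConfig(_Section):
    fwhm_cm1: Mapping[str, float] = Field(
        default_factory=lambda: dict(DISORDER_PRESETS["wscp"])
    )
    correlated: bool = False
    n_samples: int = Field(1000, ge=1)
    seed: int = 7

    @field_validator("fwhm_cm1")
    @classmethod
    def _nonnegative(cls, v):
        v = dict(v)
        for key, val in v.items():
            if key not in (QY, QX, BY, BX):
                raise ValueError(f"unknown state label {key!r} in disorder FWHM")
            if val < 0:
                raise ValueError(f"negative FWHM for {key}")
        return v


class CouplingConfig(_Section):
    j_qyqy_cm1: float = 83.0
    mask: Literal["all", "zero-zero", "none"] = "all"


class GeometryConfig(_Section):
    kind: Literal["open-sandwich", "table", "pdb"] = "open-sandwich"
    path: Optional[str] = None
    distance_angstrom: float = Field(10.836, gt=3.0)
    twist_deg: float = -94.06748
    tilt_deg: float = 32.336529
    spin_deg: float = 131.362901
    center_polar_deg: float = 119.421187
    center_azimuth_deg: float = -160.987601
    rotations_deg: Mapping[str, float] = Field(
        default_factory=lambda: dict(geometry_mod.DEFAULT_ROTATIONS)
    )

    @field_validator("rotations_deg")
    @classmethod
    def _known_labels(cls, v):
        v = dict(v)
        for key in v:
            if key not in (QY, QX, BY, BX):
                raise ValueError(f"unknown state label {key!r} in rotations")
        return v


class GridConfig(_Section):
    n_points: int = Field(32768, ge=1024)
    dt_cm: float = Field(1.0 / 16384.0, gt=0)
    tau_max_fs: float = Field(3000.0, gt=0)
    window_cm1: tuple[float, float] = (-2000.0, 12000.0)

    @field_validator("n_points")
    @classmethod
    def _power_of_two(cls, v):
        if v & (v - 1):
            raise ValueError("n_points must be a power of two")
        return v


class RunConfig(_Section):
    system: Literal["monomer", "dimer"] = "dimer"
    states: StatesConfig = StatesConfig()
    modes: ModesConfig = ModesConfig()
    vc_mode: VcModeConfig = VcModeConfig()
    bath: BathConfig = BathConfig()
    disorder: DisorderConfig = DisorderConfig()
    coupling: CouplingConfig = CouplingConfig()
    geometry: GeometryConfig = GeometryConfig()
    grid: GridConfig = GridConfig()


_PRESETS: dict[str, dict] = {
    "wscp": {
        "system": "dimer",
        "states": {"qy_energy_absolute_cm1": 14940.0},
        "disorder": {"fwhm_cm1": DISORDER_PRESETS["wscp"]},
    },
    "ether": {
        "system": "monomer",
        "states": {"qy_energy_absolute_cm1": 14910.0},
        "disorder": {"fwhm_cm1": DISORDER_PRESETS["ether-like"]},
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def preset_config(name: str = "wscp") -> RunConfig:
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return RunConfig.model_validate(_PRESETS[name])


def load_config(path: str | Path | None = None, preset: str | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    A missing or empty file resolves to the default preset (``wscp``).  A
    top-level ``preset`` key selects the base parameter set; all other keys
    override it.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config root must be a mapping")
        data = loaded
    name = data.pop("preset", None) or preset or "wscp"
    base = _PRESETS.get(name)
    if base is None:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return RunConfig.model_validate(_deep_merge(base, data))


def dump_resolved(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved parameter set (for provenance)."""
    payload = config.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# Ablation variants
# ---------------------------------------------------------------------------


def apply_variant(config: RunConfig, name: str) -> RunConfig:
    """Return a config modified for one of the named model ablations."""
    data = config.model_dump()
    states = data["states"]
    vc = data["vc_mode"]
    if name == "qy-electronic":
        states.update(include_qx=False, include_b=False)
        data["modes"]["catalog"] = "none"
        vc.update(coupling_cm1=0.0, max_quanta=0)
    elif name == "qy-vibrations":
        states.update(include_qx=False, include_b=False)
        vc.update(coupling_cm1=0.0, max_quanta=0)
    elif name == "qy-qx":
        states.update(include_b=False)
        vc.update(coupling_cm1=0.0, max_quanta=0)
    elif name == "vibronic":
        states.update(include_b=False)
    elif name == "full":
        pass
    elif name == "vibronic-00":
        states.update(include_b=False)
        data["coupling"]["mask"] = "zero-zero"
    elif name == "full-00":
        data["coupling"]["mask"] = "zero-zero"
    else:
        raise ValueError(f"unknown ablation variant {name!r}")
    return RunConfig.model_validate(data)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_mode_catalog(config: RunConfig) -> ModeCatalog:
    modes = config.modes
    if modes.catalog == "none":
        return ModeCatalog([])
    if modes.catalog == "chla":
        return chla_mode_catalog(modes.qx_displacement_factor)
    entries = []
    for i, entry in enumerate(modes.custom):
        s_qx = entry.huang_rhys_qx
        entries.append(
            VibrationalMode(
                entry.frequency_cm1,
                {QY: entry.huang_rhys_qy,
                 QX: entry.huang_rhys_qy if s_qx is None else s_qx},
                label=f"custom{i + 1}",
            )
        )
    return ModeCatalog(entries)


def build_monomer_params(config: RunConfig) -> MonomerParams:
    s = config.states
    states = [
        ElectronicState(QY, 0.0, 1.0, has_vibrations=True, vibronically_coupled=True)
    ]
    if s.include_qx:
        states.append(
            ElectronicState(
                QX, s.delta_qx_cm1, s.f_qx,
                has_vibrations=True, vibronically_coupled=True,
            )
        )
    if s.include_b:
        states.append(ElectronicState(BY, s.delta_by_cm1, s.f_by, has_vibrations=False))
        states.append(ElectronicState(BX, s.delta_bx_cm1, s.f_bx, has_vibrations=False))
    vc = VibronicCouplingMode(
        frequency=config.vc_mode.frequency_cm1,
        coupling_constant_scaled=config.vc_mode.coupling_cm1,
        max_quanta=config.vc_mode.max_quanta,
    )
    return MonomerParams(
        states=tuple(states),
        modes=build_mode_catalog(config),
        vc_mode=vc,
        qy_energy_absolute=s.qy_energy_absolute_cm1,
        inhomogeneous_fwhm=dict(config.disorder.fwhm_cm1),
    )


def build_geometry(
    config: RunConfig,
) -> tuple[geometry_mod.PigmentGeometry, geometry_mod.PigmentGeometry]:
    geo = config.geometry
    if geo.kind == "open-sandwich":
        spec = geometry_mod.SyntheticDimerSpec(
            distance=geo.distance_angstrom,
            twist_deg=geo.twist_deg,
            tilt_deg=geo.tilt_deg,
            spin_deg=geo.spin_deg,
            center_polar_deg=geo.center_polar_deg,
            center_azimuth_deg=geo.center_azimuth_deg,
            rotations=dict(geo.rotations_deg),
        )
        return geometry_mod.make_open_sandwich(spec)
    if geo.path is None:
        raise ValueError(f"geometry kind {geo.kind!r} requires a path")
    if geo.kind == "table":
        geoms = geometry_mod.read_coordinate_table(
            geo.path, rotations=dict(geo.rotations_deg)
        )
    else:
        geoms = geometry_mod.read_pdb_pigments(
            geo.path, rotations=dict(geo.rotations_deg)
        )
    if len(geoms) < 2:
        raise ValueError("need at least two pigments for a dimer geometry")
    return geoms[0], geoms[1]


def build_couplings(config: RunConfig) -> CouplingMatrix:
    geom_a, geom_b = build_geometry(config)
    params = build_monomer_params(config)
    ratios = {st.label: st.dipole_ratio_sq for st in params.states}
    labels = tuple(st.label for st in params.states)
    return scaled_couplings(
        geom_a, geom_b, ratios, j_qyqy=config.coupling.j_qyqy_cm1, labels=labels
    )


def build_system(config: RunConfig) -> ExcitonSystem:
    params = build_monomer_params(config)
    if config.system == "monomer":
        return monomer_system(assemble_monomer(params))
    geom_a, geom_b = build_geometry(config)
    couplings = build_couplings(config)
    mon_a = assemble_monomer(params)
    mon_b = assemble_monomer(params)
    return assemble_dimer(
        mon_a, mon_b, geom_a, geom_b, couplings, coupling_mask=config.coupling.mask
    )


def build_disorder(config: RunConfig) -> DisorderModel:
    d = config.disorder
    return DisorderModel(
        fwhm=dict(d.fwhm_cm1), correlated=d.correlated,
        n_samples=d.n_samples, seed=d.seed,
    )


def build_spectral_density(config: RunConfig) -> SpectralDensity:
    b = config.bath
    density = SpectralDensity(b.s1, b.s2, b.omega1_cm1, b.omega2_cm1)
    if b.rescale_total_huang_rhys is not None:
        density = density.rescaled_total(b.rescale_total_huang_rhys)
    return density


def build_engine(config: RunConfig) -> SpectrumEngine:
    g = config.grid
    return SpectrumEngine(
        density=build_spectral_density(config),
        temperature=config.bath.temperature_k,
        tgrid=TimeGrid(g.n_points, g.dt_cm),
        tau_max_fs=g.tau_max_fs,
        window=tuple(g.window_cm1),
    )
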