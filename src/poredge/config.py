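"""Run configuration: schema validation and YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    EnvironmentParameters,
    LipidParameters,
    available_lipids,
    default_environment,
    get_lipid,
    make_lipid,
)


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


@dataclass
class RunConfig:
    lipid: LipidParameters
    env: EnvironmentParameters
    r_min: float = 0.05
    r_max: float = 50.0
    r_points: int | None = None  # None -> default non-uniform grid
    L_step: float = 0.1
    out_dir: str = "."
    plot: bool = False
    verbosity: int = 1

    def r_grid(self):
        from .trajectory import default_r_grid

        if self.r_points is None:
            g = default_r_grid(self.r_max)
            return g[g >= self.r_min]
        return np.linspace(self.r_min, self.r_max, self.r_points)


def _lipid_from_spec(spec) -> LipidParameters:
    if isinstance(spec, str):
        try:
            return get_lipid(spec)
        except KeyError as exc:
            raise ConfigError(f"lipid: {exc.args[0]}") from None
    if isinstance(spec, dict):
        if "name" in spec and len(spec) == 1:
            return _lipid_from_spec(spec["name"])
        required = {"B_kBT", "KA_mN_per_m", "h_nm"}
        missing = required - set(spec)
        if missing:
            raise ConfigError(f"lipid: missing field(s) {sorted(missing)}")
        try:
            return make_lipid(
                spec.get("name", "custom"),
                float(spec["B_kBT"]),
                float(spec["KA_mN_per_m"]),
                float(spec["h_nm"]),
                float(spec.get("J0_per_nm", 0.0)),
                float(spec.get("Kt_mN_per_m", 40.0)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"lipid: {exc}") from None
    raise ConfigError("lipid: expected a registry name or a parameter mapping")


def _env_from_spec(spec) -> EnvironmentParameters:
    spec = spec or {}
    if not isinstance(spec, dict):
        raise ConfigError("environment: expected a mapping")
    known = {"sigma0_mN_per_m", "sigma_h_mN_per_m", "xi_h_nm"}
    unknown = set(spec) - known
    if unknown:
        raise ConfigError(f"environment: unknown field(s) {sorted(unknown)}")
    try:
        return default_environment(
            float(spec.get("sigma0_mN_per_m", 0.0)),
            float(spec.get("sigma_h_mN_per_m", 36.0)),
            float(spec.get("xi_h_nm", 1.0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"environment: {exc}") from None


def load_config(data: dict) -> RunConfig:
    """Validate a configuration mapping (already parsed from YAML/JSON)."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    if "lipid" not in data:
        raise ConfigError("lipid: required field is missing "
                          f"(registry names: {', '.join(available_lipids())})")
    lipid = _lipid_from_spec(data["lipid"])
    env = _env_from_spec(data.get("environment"))
    scan = data.get("scan", {}) or {}
    if not isinstance(scan, dict):
        raise ConfigError("scan: expected a mapping")
    cfg = RunConfig(
        lipid=lipid,
        env=env,
        r_min=float(scan.get("r_min", 0.05)),
        r_max=float(scan.get("r_max", 50.0)),
        r_points=scan.get("r_points"),
        L_step=float(scan.get("L_step", 0.1)),
        out_dir=str(data.get("out_dir", ".")),
        plot=bool(data.get("plot", False)),
        verbosity=int(data.get("verbosity", 1)),
    )
    if cfg.r_min <= 0 or cfg.r_max <= cfg.r_min:
        raise ConfigError("scan: need 0 < r_min < r_max")
    return cfg


def load_config_file(path: str) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return load_config(data)
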