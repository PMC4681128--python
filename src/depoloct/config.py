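"""Serializable run configuration and manifest writing."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    ``input`` is either a container base path or a phantom preset name;
    ``kernel_x``/``kernel_z`` configure the spatial estimator, ``n_bands`` /
    ``band_centers_nm`` / ``band_fwhm_nm`` the spectral one.
    """

    input: str = "two-layer"
    method: str = "spectral"
    kernel_x: int = 8
    kernel_z: int = 5
    n_bands: int = 3
    band_centers_nm: list[float] = field(default_factory=lambda: [820.0, 840.0, 860.0])
    band_fwhm_nm: float = 20.0
    threshold_db: float = 15.0
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the effective configuration (plus package version) as a YAML manifest."""
    from . import __version__

    payload = {"config": config.to_dict(), "version": __version__}
    if extra:
        payload["run"] = extra
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
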