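"""Configuration: dataset registry, analysis thresholds, retrieval stubs.

A config file is a YAML document::

    data_root: /path/to/data
    datasets:
      ceres:      {path: ceres.csv, schema_kind: matrix, release_label: 21Q2}
      mutations:  {path: mutations.csv, schema_kind: mutations}
    thresholds:
      de_alpha: 0.01
      bf_cutoff: 5.0

Omitted thresholds take the package defaults.  Dataset paths are resolved
relative to ``data_root``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError, ValidationError

SCHEMA_KINDS = frozenset(
    {"matrix", "mutations", "sample_info", "localization", "complexes"}
)

#: Default analysis thresholds.  de_alpha: BH-adjusted significance level for
#: differential expression.  ess_alpha: raw-p significance for differential
#: essentiality.  sex_ess_alpha: looser essentiality threshold used in the
#: sex-disparity workflow.  bf_cutoff: Bayes-factor binarization cutoff
#: (BF > 5 = essential).  loc_min_score: minimum summed localization
#: confidence (0-12 scale) for surface-target nomination.  var_band: variance
#: percentile band for selecting variably essential genes.
DEFAULT_THRESHOLDS: dict[str, Any] = {
    "de_alpha": 0.01,
    "ess_alpha": 0.01,
    "sex_ess_alpha": 0.05,
    "bf_cutoff": 5.0,
    "loc_min_score": 6,
    "var_band": (0.85, 0.95),
}


@dataclass(frozen=True)
class DatasetEntry:
    name: str
    path: Path
    schema_kind: str
    release_label: str = "unversioned"

    def exists(self) -> bool:
        return self.path.is_file()


@dataclass(frozen=True)
class RetrievalStub:
    """Registry entry for a remote release.

    Live downloads are out of scope; the registry records the contract
    (URL + checksum) so a retrieval layer can be attached without touching
    the analysis code.  Public release data carries a CC Attribution 4.0
    license; downstream users accept it when they fetch the data.
    """

    name: str
    url: str
    sha256: str = ""
    release_label: str = "latest"


@dataclass
class Config:
    data_root: Path
    datasets: dict[str, DatasetEntry] = field(default_factory=dict)
    thresholds: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    retrieval: dict[str, RetrievalStub] = field(default_factory=dict)

    def threshold(self, key: str) -> Any:
        return self.thresholds[key]

    def dataset_path(self, name: str) -> Path:
        return self.datasets[name].path

    def content_hash(self) -> str:
        """Stable hash of the resolved configuration, for provenance."""
        parts = [str(self.data_root)]
        for name in sorted(self.datasets):
            d = self.datasets[name]
            parts.append(f"{name}:{d.path}:{d.schema_kind}:{d.release_label}")
        for key in sorted(self.thresholds):
            parts.append(f"{key}={self.thresholds[key]}")
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def _validate_thresholds(thresholds: dict[str, Any]) -> dict[str, Any]:
    out = dict(DEFAULT_THRESHOLDS)
    for key, value in thresholds.items():
        if key not in DEFAULT_THRESHOLDS:
            raise ValidationError(f"unknown threshold key: {key!r}")
        if key == "var_band":
            try:
                lo, hi = (float(v) for v in value)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"threshold 'var_band' must be two numbers: {value!r}") from exc
            if not (0.0 <= lo < hi <= 1.0):
                raise ValidationError(
                    f"threshold 'var_band' must satisfy 0 <= lower < upper <= 1, got {(lo, hi)}"
                )
            out[key] = (lo, hi)
        else:
            try:
                out[key] = type(DEFAULT_THRESHOLDS[key])(value)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"threshold {key!r} is not numeric: {value!r}") from exc
            if "alpha" in key and not (0.0 < out[key] <= 1.0):
                raise ValidationError(f"threshold {key!r} must lie in (0, 1], got {out[key]}")
    return out


def load_config(path: str | Path) -> Config:
    """Read a YAML config file, fill threshold defaults, resolve paths.

    Raises
    ------
    ConfigError
        If the file is missing or not a mapping.
    ValidationError
        If a threshold is malformed (non-numeric, reversed band) or a dataset
        entry has an unknown ``schema_kind``; the message names the key.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config file is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    data_root = Path(raw.get("data_root", path.parent))
    if not data_root.is_absolute():
        data_root = (path.parent / data_root).resolve()

    datasets: dict[str, DatasetEntry] = {}
    for name, entry in (raw.get("datasets") or {}).items():
        if not isinstance(entry, dict) or "path" not in entry:
            raise ValidationError(f"dataset {name!r} must be a mapping with a 'path' key")
        kind = entry.get("schema_kind", "matrix")
        if kind not in SCHEMA_KINDS:
            raise ValidationError(
                f"dataset {name!r} has unknown schema_kind {kind!r}; "
                f"expected one of {sorted(SCHEMA_KINDS)}"
            )
        p = Path(entry["path"])
        if not p.is_absolute():
            p = data_root / p
        datasets[name] = DatasetEntry(
            name=name, path=p, schema_kind=kind,
            release_label=str(entry.get("release_label", "unversioned")),
        )

    retrieval = {
        name: RetrievalStub(
            name=name, url=str(entry.get("url", "")),
            sha256=str(entry.get("sha256", "")),
            release_label=str(entry.get("release_label", "latest")),
        )
        for name, entry in (raw.get("retrieval") or {}).items()
    }

    thresholds = _validate_thresholds(raw.get("thresholds") or {})
    return Config(data_root=data_root, datasets=datasets,
                  thresholds=thresholds, retrieval=retrieval)


def validate_config(config: Config) -> list[str]:
    """Return a list of problems (empty = valid): every dataset entry must
    name an existing, readable file."""
    problems = []
    for name, entry in config.datasets.items():
        if not entry.exists():
            problems.append(f"dataset {name!r}: file not found: {entry.path}")
    return problems
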