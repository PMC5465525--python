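"""Declarative run configuration: one YAML file plus command-line overrides.

The secret is never placed in the config file or argv; it is read from an
environment variable (default ``PPRLINK_SECRET``) or a key file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .encoding import EncodingConfig
from .errors import ConfigError
from .records import ParameterSet, identity_column_map, parameter_set

DEFAULT_SECRET_ENV = "PPRLINK_SECRET"


@dataclass
class RunConfig:
    """Merged view of the config file and command-line overrides."""

    column_map: dict = field(default_factory=identity_column_map)
    parameter_set: str = "set1"
    gram_modes: dict = field(default_factory=dict)
    padding: bool = True
    l: int = 1000
    k: int = 10
    scheme: str = "random_hashing"
    salt_field: str | None = None
    field_tagging: bool = True
    positional_unigrams: bool = False
    secret_env: str = DEFAULT_SECRET_ENV
    secret_file: str | None = None
    delimiter: str = ","
    threshold: float = 0.85
    leaf_limit: int = 1

    def resolve_secret(self) -> str:
        if self.secret_file:
            with open(self.secret_file) as fh:
                secret = fh.read().strip()
            if not secret:
                raise ConfigError(f"secret file {self.secret_file!r} is empty")
            return secret
        secret = os.environ.get(self.secret_env, "")
        if not secret:
            raise ConfigError(
                f"no secret: set ${self.secret_env} or configure secret_file"
            )
        return secret

    def pset(self) -> ParameterSet:
        return parameter_set(
            self.parameter_set, gram_modes=self.gram_modes, padding=self.padding
        )

    def encoding_config(self) -> EncodingConfig:
        return EncodingConfig(
            secret=self.resolve_secret(),
            l=self.l,
            k=self.k,
            scheme=self.scheme,
            salt_field=self.salt_field,
            field_tagging=self.field_tagging,
            positional_unigrams=self.positional_unigrams,
        )

    def summary(self) -> str:
        """Loggable echo of the effective config (never includes the secret)."""
        return (
            f"pset={self.parameter_set} l={self.l} k={self.k} scheme={self.scheme} "
            f"padding={self.padding} field_tagging={self.field_tagging} "
            f"positional_unigrams={self.positional_unigrams} "
            f"salt_field={self.salt_field} threshold={self.threshold} "
            f"leaf_limit={self.leaf_limit}"
        )


def load_config(path: str | None, **overrides) -> RunConfig:
    """Load YAML config (if any) and apply non-None command-line overrides."""
    data: dict = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path!r} must be a mapping")
    if "secret" in data:
        raise ConfigError("secrets must not be placed in the config file")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(data)
    for key, val in overrides.items():
        if val is not None:
            if key not in known:
                raise ConfigError(f"unknown override {key!r}")
            merged[key] = val
    return RunConfig(**merged)
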