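"""Provenance-tagged parameter registry.

Parameters live in YAML files mapping name -> {value, units, source} with
source in {paper, literature, calibrated}.  ``load_params`` returns a
:class:`ParamRegistry` whose attributes are the plain values; the full
records stay available for provenance logging.
"""

from __future__ import annotations

from importlib import resources

import yaml

VALID_SOURCES = {"paper", "literature", "calibrated"}


class ParamRegistry:
    def __init__(self, records: dict):
        self._records = {}
        for name, rec in records.items():
            if not isinstance(rec, dict) or "value" not in rec:
                raise ValueError(f"registry entry {name!r} missing 'value'")
            src = rec.get("source", "literature")
            if src not in VALID_SOURCES:
                raise ValueError(f"registry entry {name!r}: bad source {src!r}")
            self._records[name] = dict(rec)

    def __getattr__(self, name):
        try:
            return self._records[name]["value"]
        except KeyError:
            raise AttributeError(name)

    def __getitem__(self, name):
        return self._records[name]["value"]

    def __contains__(self, name):
        return name in self._records

    def record(self, name) -> dict:
        return dict(self._records[name])

    def names(self):
        return sorted(self._records)

    def set(self, name, value, source="calibrated", units=None):
        rec = self._records.setdefault(name, {"units": units or "-"})
        rec["value"] = value
        rec["source"] = source

    def override(self, overrides: dict):
        """Apply {name: value} overrides (marked source=calibrated)."""
        for name, value in (overrides or {}).items():
            if name not in self._records:
                raise KeyError(f"unknown parameter {name!r}")
            self._records[name]["value"] = value
            self._records[name]["source"] = "calibrated"
        return self

    def provenance_table(self):
        return [
            {"name": n, **self._records[n]} for n in self.names()
        ]


def load_params(package: str = "ngvu.synapse", filename: str = "defaults.yaml",
                overrides: dict | None = None) -> ParamRegistry:
    text = resources.files(package).joinpath(f"params/{filename}").read_text()
    reg = ParamRegistry(yaml.safe_load(text))
    if overrides:
        reg.override(overrides)
    return reg
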