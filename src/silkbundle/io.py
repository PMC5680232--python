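"""Input validation, structured configs and run manifests.

Formats are deliberately plain: 2-column CSV for curves and spectra, JSON
for topology, YAML for configs.  ``validate_inputs`` gives line/column
diagnostics and reports at most the first five violations.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone

import numpy as np
import yaml

from .dynamics import SimulationConfig
from .forcefield import ForceFieldParams

__all__ = ["ValidationError", "validate_inputs", "RunManifest",
           "write_manifest", "load_config", "dump_config"]


class ValidationError(ValueError):
    def __init__(self, violations):
        self.violations = violations[:5]
        super().__init__("validation failed:\n" +
                         "\n".join(f"  - {v}" for v in self.violations))


def _validate_curve_csv(path):
    violations = []
    seen_header = False
    prev = -np.inf
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if not seen_header:
                cols = [c.strip() for c in s.split(",")]
                if cols[0] != "strain":
                    violations.append(f"line {ln}: expected 'strain' header column")
                seen_header = True
                continue
            parts = s.split(",")
            if len(parts) < 2:
                violations.append(f"line {ln}: need 2 columns")
                continue
            try:
                e, st = float(parts[0]), float(parts[1])
            except ValueError:
                violations.append(f"line {ln}: non-numeric value")
                continue
            if e < 0:
                violations.append(f"line {ln}: negative strain {e}")
            if e <= prev:
                violations.append(f"line {ln}: strain not strictly increasing")
            if not np.isfinite(st):
                violations.append(f"line {ln}: non-finite stress")
            prev = e
    if not seen_header:
        violations.append("no header row found")
    return violations


def _validate_spectrum_csv(path):
    violations = []
    seen_header = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if not seen_header:
                seen_header = True
                continue
            parts = s.split(",")
            if len(parts) < 2:
                violations.append(f"line {ln}: need 2 columns")
                continue
            try:
                w, a = float(parts[0]), float(parts[1])
            except ValueError:
                violations.append(f"line {ln}: non-numeric value")
                continue
            if w <= 0:
                violations.append(f"line {ln}: non-positive wavenumber")
            if not np.isfinite(a):
                violations.append(f"line {ln}: non-finite absorbance")
    return violations


def _validate_topology_json(path):
    violations = []
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        return [f"not valid JSON: {e}"]
    required = ["positions_um", "fibril_index", "bonds", "alive"]
    for key in required:
        if key not in doc:
            violations.append(f"missing key '{key}'")
    if violations:
        return violations
    n = len(doc["positions_um"])
    alive = doc["alive"]
    for b, pair in enumerate(doc["bonds"]):
        for i in pair:
            if not 0 <= i < n:
                violations.append(f"bond {b} references missing bead {i}")
            elif not alive[i]:
                violations.append(f"bond {b} references deleted bead {i}")
    for key in ("fixed_ids", "pulled_ids"):
        for i in doc.get(key, []):
            if not 0 <= i < n or not alive[i]:
                violations.append(f"{key} references missing/deleted bead {i}")
    return violations


_VALIDATORS = {
    "curve": _validate_curve_csv,
    "spectrum": _validate_spectrum_csv,
    "topology": _validate_topology_json,
}


def validate_inputs(path, expected_format: str) -> dict:
    """Schema check; raises :class:`ValidationError` listing <= 5 violations."""
    if expected_format not in _VALIDATORS:
        raise ValueError(f"unknown format '{expected_format}' "
                         f"(choose from {sorted(_VALIDATORS)})")
    violations = _VALIDATORS[expected_format](path)
    if violations:
        raise ValidationError(violations)
    return {"path": str(path), "format": expected_format, "ok": True}


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------

def load_config(path) -> tuple[ForceFieldParams, SimulationConfig, dict]:
    """YAML config with [forcefield]/[loading] sections; defaults otherwise."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    ff = ForceFieldParams(**doc.get("forcefield", {}))
    cfg = SimulationConfig(**doc.get("loading", {}))
    return ff, cfg, doc


def dump_config(path, ff: ForceFieldParams, cfg: SimulationConfig,
                extra: dict | None = None) -> None:
    doc = {"forcefield": asdict(ff), "loading": asdict(cfg)}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


class RunManifest:
    """Provenance record: resolved config, seeds, versions, file digests."""

    def __init__(self, command: str, config: dict, seeds, inputs=(), outputs=()):
        from . import __version__
        self.doc = {
            "command": command,
            "silkbundle_version": __version__,
            "python": platform.python_version(),
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "seeds": list(np.atleast_1d(seeds).astype(int).tolist()),
            "config": config,
            "inputs": {str(p): _digest(p) for p in inputs},
            "outputs": {str(p): _digest(p) for p in outputs},
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.doc, fh, indent=2, default=str)


def write_manifest(outdir, command, config, seeds, inputs=(), outputs=()):
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = RunManifest(command, config, seeds, inputs, outputs)
    m.write(outdir / "manifest.json")
    return m
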