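"""Characterization report assembly and the end-to-end pipeline.

``run_pipeline`` executes decay fitting → thermodynamics → purification
→ gel calibration as configured and assembles a
:class:`CharacterizationReport` that serializes to JSON losslessly.
Numbers are stored at full precision; display rounding (2 decimals, the
convention of published tables) is applied only by ``rounded()`` views.
The report is deterministic given inputs and seed; the timestamp is
isolated in provenance and excluded from equality.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .errors import ValidationError
from .gel import GelCalibration, calibrate, estimate_mw, read_markers_csv
from .io import (
    arrhenius_summary,
    file_sha256,
    fits_frame,
    read_fits_csv,
    read_timecourses_csv,
    thermo_frame,
)
from .kinetics import fit_first_order
from .purification import build_ledger, read_ledger_csv
from .simulate import SimulationScenario, simulate_study
from .thermo import thermo_profile


@dataclass
class CharacterizationReport:
    """Full enzyme-characterization result set.

    ``provenance`` carries input hashes, seed and package version; its
    ``timestamp`` key is informational and ignored by ``__eq__``.
    """

    arrhenius: dict | None = None
    profiles: list[dict] = field(default_factory=list)
    fits: list[dict] = field(default_factory=list)
    purification: list[dict] = field(default_factory=list)
    gel: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "CharacterizationReport":
        return cls(**json.loads(text))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterizationReport):
            return NotImplemented
        def strip(d: dict) -> dict:
            prov = {k: v for k, v in d.get("provenance", {}).items() if k != "timestamp"}
            return {**d, "provenance": prov}
        return strip(asdict(self)) == strip(asdict(other))


def _round_tree(obj: Any, ndigits: int = 2) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_tree(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_tree(v, ndigits) for v in obj]
    return obj


def rounded(report: CharacterizationReport, ndigits: int = 2) -> dict:
    """Display view with report-style rounding; never used for computation."""
    return _round_tree(asdict(report), ndigits)


def run_pipeline(config: Mapping[str, Any]) -> CharacterizationReport:
    """Execute the configured analysis stages.

    Recognized config keys (all optional except one source of kinetics):

    - ``scenario``: mapping of :class:`SimulationScenario` fields — the
      synthetic study to generate and analyze; or
    - ``timecourses_csv``: residual-activity courses to fit; or
    - ``fits_csv``: pre-fitted (temperature, kd) pairs.
    - ``ledger_csv``: purification ledger.
    - ``markers_csv`` + ``query_rf``: gel calibration and a band query.
    - ``kd_units``: "per_min" (default) or "per_sec" for ΔG.
    - ``seed``: overrides the scenario seed.
    """
    report = CharacterizationReport()
    hashes: dict[str, str] = {}
    kd_units = config.get("kd_units", "per_min")
    seed = config.get("seed")

    pairs = None
    if "scenario" in config:
        params = dict(config["scenario"] or {})
        if seed is not None:
            params["seed"] = int(seed)
        scenario = SimulationScenario(**params)
        conditions = config.get("conditions", ("control",))
        courses = simulate_study(scenario, conditions)
        fits = [fit_first_order(c) for c in courses]
        report.fits = fits_frame(fits).to_dict("records")
        pairs = [
            (f.temperature_c, f.kd)
            for f in fits
            if f.condition == "control" and not f.non_decaying
        ]
    elif "timecourses_csv" in config:
        path = config["timecourses_csv"]
        hashes[str(path)] = file_sha256(path)
        courses = read_timecourses_csv(path)
        fits = [fit_first_order(c) for c in courses]
        report.fits = fits_frame(fits).to_dict("records")
        pairs = [(f.temperature_c, f.kd) for f in fits if not f.non_decaying]
    elif "fits_csv" in config:
        path = config["fits_csv"]
        hashes[str(path)] = file_sha256(path)
        pairs = read_fits_csv(path)

    if pairs is not None:
        if len({t for t, _ in pairs}) < 2:
            raise ValidationError("pipeline needs kd at ≥2 distinct temperatures")
        arr, profiles = thermo_profile(pairs, kd_units=kd_units)
        report.arrhenius = arrhenius_summary(arr)
        report.profiles = thermo_frame(profiles).to_dict("records")

    if "ledger_csv" in config:
        path = config["ledger_csv"]
        hashes[str(path)] = file_sha256(path)
        steps = read_ledger_csv(path)
        report.purification = [asdict(s) for s in steps]
    elif "ledger" in config:
        steps = build_ledger(config["ledger"])
        report.purification = [asdict(s) for s in steps]

    if "markers_csv" in config:
        path = config["markers_csv"]
        hashes[str(path)] = file_sha256(path)
        markers = read_markers_csv(path)
        model = calibrate(markers)
        gel: dict[str, Any] = {
            "slope": model.slope,
            "intercept": model.intercept,
            "r_squared": model.r_squared,
            "rf_range": list(model.rf_range),
        }
        if "query_rf" in config:
            rf = float(config["query_rf"])
            gel["query_rf"] = rf
            gel["estimated_mw_kda"] = estimate_mw(model, rf)
        report.gel = gel

    if report.arrhenius is None and not report.purification and report.gel is None:
        raise ValidationError(
            "pipeline config selected no analysis (provide scenario, "
            "timecourses_csv, fits_csv, ledger_csv or markers_csv)"
        )

    report.provenance = {
        "package": "thermokin",
        "version": __version__,
        "seed": seed,
        "kd_units": kd_units,
        "input_sha256": hashes,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    return report
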