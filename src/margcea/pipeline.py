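"""End-to-end orchestration: one config in, a reproducible bundle out.

The pipeline runs generate/ingest → reconstruct → fit → two-arm cohort
runs → incremental statistics → one-way DSA → PSA → CEAC → price
threshold, and writes every artifact as CSV/JSON plus a manifest with
SHA-256 checksums. Survival inputs come either from the calibrated
synthetic generators (``synthetic`` block) or from digitized curve and
risk-table CSV files (``files`` block) — exactly one per run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import WTP
from .ipd_reconstruction import reconstruct_ipd
from .model import ARMS, TwoArmModel, build_synthetic_fits
from .sensitivity import (build_param_specs, ceac, one_way_dsa, price_threshold,
                          run_psa)
from .survival_models import fit_parametric
from .synthetic_data import DigitizedCurve, RiskTable

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

logger = logging.getLogger(__name__)

_ENDPOINT_FAMILY = {"PFS": "loglogistic", "OS": "weibull"}

#: Recorded in every manifest: transcription corrections applied to inputs.
DATA_CORRECTIONS = [
    "US anemia management cost read as 14,636.53 "
    "(source prints '146,36.53'; range 11,709.22-17,563.84)",
]


class ConfigError(ValueError):
    """Invalid run configuration (reported with the offending key path)."""


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``synthetic`` (generator settings) or ``files``
    (mapping arm → endpoint → {curve, risk} CSV paths) must be present.
    """

    country: str
    seed: int
    output_dir: Path
    synthetic: dict | None = None
    files: dict | None = None
    psa_iterations: int = 1000
    wtp: float | None = None
    currency_note: str = "2021 USD, 6.45 CNY/USD"

    def __post_init__(self):
        if self.country not in ("US", "CN"):
            raise ConfigError("/country: must be 'US' or 'CN'")
        if self.seed is None:
            raise ConfigError("/seed: mandatory")
        if (self.synthetic is None) == (self.files is None):
            raise ConfigError(
                "/synthetic,/files: exactly one survival-input block required")
        if self.psa_iterations < 1:
            raise ConfigError("/psa_iterations: must be >= 1")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("/: config must be a mapping")
        known = {"country", "seed", "output_dir", "synthetic", "files",
                 "psa_iterations", "wtp", "currency_note"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"/{sorted(unknown)[0]}: unknown key")
        missing = {"country", "seed", "output_dir"} - set(raw)
        if missing:
            raise ConfigError(f"/{sorted(missing)[0]}: required")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fits_from_files(files: dict) -> dict:
    fits: dict = {arm: {} for arm in ARMS}
    for arm in ARMS:
        if arm not in files:
            raise ConfigError(f"/files/{arm}: required")
        for endpoint in ("PFS", "OS"):
            block = files[arm].get(endpoint)
            if not block or "curve" not in block:
                raise ConfigError(f"/files/{arm}/{endpoint}/curve: required")
            curve = DigitizedCurve.from_csv(block["curve"])
            risk = RiskTable.from_csv(block["risk"]) if block.get("risk") else None
            rec = reconstruct_ipd(curve, risk, total_events=block.get("total_events"),
                                  arm_label=arm, endpoint=endpoint)
            fits[arm][endpoint] = fit_parametric(rec.ipd, _ENDPOINT_FAMILY[endpoint])
    return fits


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest dictionary (also written to manifest.json).
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    def save_json(obj, name: str):
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        written.append(path)

    if config.synthetic is not None:
        syn = dict(config.synthetic)
        fits = build_synthetic_fits(
            n_patients=int(syn.get("n_patients", 20_000)),
            base_seed=int(config.seed),
            reconstruct=bool(syn.get("reconstruct", True)),
        )
    else:
        fits = _fits_from_files(config.files)

    model = TwoArmModel(country=config.country, fits=fits, wtp=config.wtp)
    save_json({arm: {ep: f.to_dict() for ep, f in d.items()}
               for arm, d in fits.items()}, "fits.json")

    results = {}
    for arm in ARMS:
        res = model.evaluate_arm(arm, keep_trace=True)
        results[arm] = res
        save_df(res.trace, f"trace_{arm}.csv")
    _, ce = model.evaluate()
    save_json({
        "country": config.country,
        "currency_note": config.currency_note,
        "arms": {arm: results[arm].to_dict() for arm in ARMS},
        "incremental": ce.to_dict(),
    }, "results.json")

    specs = build_param_specs(model.country)
    tornado = one_way_dsa(model, specs)
    import pandas as pd
    save_df(pd.DataFrame(
        [{"param": e.name, "icer_low": e.icer_at_low,
          "icer_high": e.icer_at_high, "swing": e.swing} for e in tornado]),
        "tornado.csv")

    psa = run_psa(model, n_iter=config.psa_iterations, seed=config.seed)
    save_df(psa.to_frame(), "psa.csv")
    save_df(ceac(psa), "ceac.csv")

    threshold = price_threshold(model)
    save_json({
        "target_drug": "margetuximab",
        "wtp": model.wtp,
        "price_reduction_fraction": threshold,
    }, "threshold.json")

    manifest = {
        "software_version": __version__,
        "seed": config.seed,
        "country": config.country,
        "config_hash": hashlib.sha256(
            json.dumps({
                "country": config.country, "seed": config.seed,
                "synthetic": config.synthetic, "files": config.files,
                "psa_iterations": config.psa_iterations, "wtp": config.wtp,
            }, sort_keys=True, default=str).encode()).hexdigest(),
        "currency_note": config.currency_note,
        "data_corrections": DATA_CORRECTIONS,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    save_json(manifest, "manifest.json")
    return manifest
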