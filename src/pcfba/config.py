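"""Run configuration: a flat key-value file with sections, and the driver
that turns one config into a full set of result artifacts.

Example config::

    [run]
    model = model.json        ; path, or "toy" for the bundled network
    output = results/
    seed = 1

    [condition]
    mu = 0.2:0.7:6            ; a single value or start:stop:n grid
    glucose = limited         ; "limited" (binary search) or "rich"

    [tolerance]
    s_rel = 1e-6
    mu_rel = 1e-4

    [perturbation]
    delta_q = 0.01
    delta_c = 0.01
    robustness_factor = 2.0

Unknown keys are rejected.  Outputs are deterministic functions of
(config, seed): per-mu TSV tables, a JSON manifest carrying the config
hash and solver statuses, and a log file.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .fixtures import make_toy_pcmodel
from .io import load_model, result_frame
from .simulation import (
    GrowthInfeasibleError,
    max_growth_rate,
    min_glucose_concentration,
)

__all__ = ["RunConfig", "ConfigError", "run", "EXIT_CONFIG", "EXIT_INFEASIBLE"]

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_INFEASIBLE = 3

_KNOWN = {
    "run": {"model", "output", "seed"},
    "condition": {"mu", "glucose", "blocked"},
    "tolerance": {"s_rel", "mu_rel"},
    "perturbation": {"delta_q", "delta_c", "robustness_factor"},
}


class ConfigError(ValueError):
    """Malformed run configuration; the message names the offending key."""


@dataclass
class RunConfig:
    model: str = "toy"
    output: str = "pcfba_out"
    seed: int = 0
    mu: list[float] = field(default_factory=lambda: [0.5])
    glucose: str = "limited"  # or "rich"
    blocked: list[str] = field(default_factory=list)
    s_rel: float = 1e-6
    mu_rel: float = 1e-4
    delta_q: float = 0.01
    delta_c: float = 0.01
    robustness_factor: float = 2.0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
        read = parser.read(str(path))
        if not read:
            raise ConfigError(f"config file not found: {path}")
        for section in parser.sections():
            if section not in _KNOWN:
                raise ConfigError(f"unknown section [{section}]")
            for key in parser[section]:
                if key not in _KNOWN[section]:
                    raise ConfigError(f"unknown key {key!r} in [{section}]")
        cfg = cls()
        run_s = parser["run"] if parser.has_section("run") else {}
        cfg.model = run_s.get("model", cfg.model)
        cfg.output = run_s.get("output", cfg.output)
        try:
            cfg.seed = int(run_s.get("seed", cfg.seed))
        except ValueError as exc:
            raise ConfigError(f"seed: {exc}") from exc
        if parser.has_section("condition"):
            sec = parser["condition"]
            if "mu" in sec:
                cfg.mu = _parse_grid(sec["mu"])
            cfg.glucose = sec.get("glucose", cfg.glucose)
            if cfg.glucose not in ("limited", "rich"):
                raise ConfigError(f"glucose must be limited|rich, got {cfg.glucose!r}")
            if "blocked" in sec:
                cfg.blocked = [t for t in sec["blocked"].split(",") if t]
        if parser.has_section("tolerance"):
            sec = parser["tolerance"]
            cfg.s_rel = float(sec.get("s_rel", cfg.s_rel))
            cfg.mu_rel = float(sec.get("mu_rel", cfg.mu_rel))
        if parser.has_section("perturbation"):
            sec = parser["perturbation"]
            cfg.delta_q = float(sec.get("delta_q", cfg.delta_q))
            cfg.delta_c = float(sec.get("delta_c", cfg.delta_c))
            cfg.robustness_factor = float(sec.get("robustness_factor", cfg.robustness_factor))
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _parse_grid(text: str) -> list[float]:
    text = text.strip()
    if ":" in text:
        parts = text.split(":")
        if len(parts) != 3:
            raise ConfigError(f"mu grid must be start:stop:n, got {text!r}")
        start, stop, n = float(parts[0]), float(parts[1]), int(parts[2])
        return [float(x) for x in np.linspace(start, stop, n)]
    return [float(text)]


def load_configured_model(cfg: RunConfig):
    if cfg.model == "toy":
        model = make_toy_pcmodel()
    else:
        model = load_model(cfg.model)
    if cfg.blocked:
        model.blocked_reactions = list(model.blocked_reactions) + cfg.blocked
    return model


def run(cfg: RunConfig) -> int:
    """Execute a mu-grid sweep and write TSVs, a manifest, and a log.

    Returns a process exit status: 0 on success, 3 if any condition is
    infeasible (after writing partial results and diagnostics).
    """
    out = Path(cfg.output)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pcfba")
    root.addHandler(handler)
    old_level, old_prop = root.level, root.propagate
    root.setLevel(logging.INFO)
    root.propagate = False  # bisection INFO goes to the run log, not stderr
    manifest = {
        "version": __version__,
        "config": dict(cfg.__dict__),
        "config_hash": cfg.config_hash(),
        "conditions": [],
    }
    status = EXIT_OK
    try:
        model = load_configured_model(cfg)
        summary_rows = []
        for mu in cfg.mu:
            entry: dict = {"mu": mu}
            try:
                if cfg.glucose == "limited":
                    S, res = min_glucose_concentration(model, mu, tol=cfg.s_rel)
                    entry["S_min"] = S
                else:
                    mu_max, res = max_growth_rate(model, None, tol=cfg.mu_rel)
                    entry["mu_max"] = mu_max
                entry.update(
                    sigma=res.sigma,
                    objective=res.objective,
                    inactive_enzyme=res.inactive_enzyme,
                    solver="optimal",
                )
                frame = result_frame(res, model)
                frame.to_csv(out / f"fluxes_mu_{mu:g}.tsv", sep="\t", index=False)
                ex = res.exchange_fluxes(model)
                summary_rows.append(
                    {"mu": mu, **{f"q_{k}": v for k, v in sorted(ex.items())},
                     "S": entry.get("S_min"), "inactive": res.inactive_enzyme,
                     "sigma": res.sigma}
                )
            except GrowthInfeasibleError as exc:
                entry["solver"] = f"infeasible: {exc}"
                status = EXIT_INFEASIBLE
            manifest["conditions"].append(entry)
        if summary_rows:
            import pandas as pd

            pd.DataFrame(summary_rows).to_csv(
                out / "summary.tsv", sep="\t", index=False
            )
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        root.removeHandler(handler)
        root.setLevel(old_level)
        root.propagate = old_prop
        handler.close()
    return status
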