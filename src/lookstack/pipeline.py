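"""End-to-end orchestration: simulate or ingest, derive, fit, compare, report.

One :class:`PipelineConfig` (one master seed) drives the whole run; every
random stream is derived from it deterministically, so identical configs
produce byte-identical report tables.  A single model's fit failure is
recorded and excluded from stacking rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lookstack import inference, loo, models, stacking, synthetic, variables

logger = logging.getLogger("lookstack")


@dataclasses.dataclass
class SyntheticConfig:
    """Generator settings for a pipeline run on simulated data."""

    n_individuals: int = 10
    n_days: int = 10
    focals_per_day: int = 15
    n_cliques: int = 3
    grid_n: int = 24
    true_response: str = "frequency"
    true_model_id: int = 4
    coefficients: dict = dataclasses.field(
        default_factory=lambda: {"Intercept": -1.8, "amount_eaten": 0.08}
    )
    re_sd_date: float = 0.2
    re_sd_individual: float = 0.2
    sigma: float = 4.0
    n_agonistic: int = 638
    agonistic_steepness: float = 1.0
    grooming_within_rate: float = 10.0
    grooming_between_rate: float = 1.0


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    responses: tuple = ("frequency", "duration")
    model_ids: tuple = tuple(range(1, 22))
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    dataset_path: str | None = None
    chains: int = 4
    iterations: int = 1000
    warmup: int = 500
    stacking_threshold: float = stacking.DEFAULT_RESTACK_THRESHOLD
    output_dir: str = "lookstack_output"
    full_settings: bool = False

    def validate(self) -> None:
        unknown = set(self.responses) - set(models.RESPONSES)
        if unknown:
            raise ValueError(f"unknown response(s) {sorted(unknown)}")
        bad = [m for m in self.model_ids if not 1 <= m <= 21]
        if bad:
            raise ValueError(f"model ids out of range: {bad}")
        if not self.model_ids:
            raise ValueError("no models selected")
        if not 0 < self.stacking_threshold < 1:
            raise ValueError("stacking threshold must lie in (0, 1)")
        inference.FitSettings(
            chains=self.chains, iterations=self.iterations, warmup=self.warmup
        )

    def fit_settings(self, seed: int) -> inference.FitSettings:
        if self.full_settings:
            return inference.FitSettings.full_scale(seed=seed)
        return inference.FitSettings(
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["responses"] = list(self.responses)
        d["model_ids"] = list(self.model_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "responses" in d:
            d["responses"] = tuple(d["responses"])
        if "model_ids" in d:
            d["model_ids"] = tuple(d["model_ids"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass
class PipelineReport:
    """Stacking and R2 tables per response plus provenance."""

    tables: dict[str, pd.DataFrame]
    diagnostics: pd.DataFrame
    failures: list[tuple[str, int, str]]
    config: PipelineConfig
    config_hash: str
    seed: int
    khat_summary: dict = dataclasses.field(default_factory=dict)


def _child_seed(master: int, *tags: int) -> int:
    """Deterministic sub-seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(np.array([master, *tags], dtype=np.int64).tobytes()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Data acquisition

def simulate_input_data(config: PipelineConfig):
    """Simulate roster, landscape, focals, matrices under the master seed."""
    s = config.synthetic
    seed = config.seed
    roster = synthetic.simulate_roster(
        s.n_individuals, s.n_cliques, seed=_child_seed(seed, 1)
    )
    landscape = synthetic.simulate_landscape(s.grid_n, seed=_child_seed(seed, 2))
    true_config = synthetic.TrueModelConfig(
        response=s.true_response,
        model_id=s.true_model_id,
        coefficients=dict(s.coefficients),
        re_sd_date=s.re_sd_date,
        re_sd_individual=s.re_sd_individual,
        sigma=s.sigma,
        n_individuals=s.n_individuals,
        n_days=s.n_days,
        focals_per_day=s.focals_per_day,
        n_cliques=s.n_cliques,
        grid_n=s.grid_n,
        seed=_child_seed(seed, 3),
    )
    observations = synthetic.simulate_focals(roster, landscape, true_config)

    # fill the configured response from the true model; the other response is
    # filled from a neutral intercept-only process so both model arrays fit
    spec = next(
        m
        for m in models.build_model_set(s.true_response)
        if m.model_id == s.true_model_id
    )
    observations = synthetic.generate_looking(
        observations, spec, true_config, roster, landscape
    )
    other = "duration" if s.true_response == "frequency" else "frequency"
    other_config = dataclasses.replace(
        true_config,
        response=other,
        model_id=1,
        coefficients={"Intercept": -1.8 if other == "frequency" else -20.0},
        seed=_child_seed(seed, 6),
    )
    other_spec = next(m for m in models.build_model_set(other) if m.model_id == 1)
    observations = synthetic.generate_looking(
        observations, other_spec, other_config, roster, landscape
    )

    agonistic = synthetic.simulate_agonistic_matrix(
        roster, s.n_agonistic, s.agonistic_steepness, seed=_child_seed(seed, 4)
    )
    grooming = synthetic.simulate_grooming(
        roster,
        s.grooming_within_rate,
        s.grooming_between_rate,
        seed=_child_seed(seed, 5),
    )
    return observations, roster, agonistic, grooming, landscape, true_config


def derive_tables(
    observations, roster, agonistic, grooming, landscape
) -> dict[str, object]:
    """Derived-variable stage: rank, cliques, and the analysis table."""
    ranking = variables.isi_rank(
        agonistic, ids=roster.individual_ids, seed=0
    )
    clique_map = variables.detect_cliques(grooming, ids=roster.individual_ids)
    table = variables.build_analysis_table(
        observations,
        roster,
        rank_map=ranking.rank_map(),
        clique_map=clique_map,
        layers=landscape,
    )
    return {"ranking": ranking, "clique_map": clique_map, "table": table}


def ingest_dataset(path, schema_map: dict | None = None) -> pd.DataFrame:
    """Load an external focal table, validating row invariants.

    ``schema_map`` renames external columns onto the documented schema.
    Rows violating the censoring or exposure invariants are rejected with a
    line-numbered report; models whose terms are absent from the table are
    skipped downstream with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path if path.suffix == ".csv" else path / "focals.csv")
    if schema_map:
        frame = frame.rename(columns=dict(schema_map))
    rejected = []
    if {"total_look_seconds", "in_view_seconds"} <= set(frame.columns):
        bad = frame["total_look_seconds"] > frame["in_view_seconds"] + 1e-9
        for line in frame.index[bad]:
            rejected.append((int(line) + 2, "total_look_seconds exceeds in_view_seconds"))
        frame = frame[~bad]
    if {"censored", "total_look_seconds", "in_view_seconds"} <= set(frame.columns):
        cens = frame["censored"].notna() & (
            frame["censored"].fillna(0).astype(float) != 0
        )
        at_cap = np.isclose(frame["total_look_seconds"], frame["in_view_seconds"])
        bad = cens != at_cap
        bad &= frame["total_look_seconds"].notna()
        for line in frame.index[bad]:
            rejected.append((int(line) + 2, "censored flag inconsistent with duration"))
        frame = frame[~bad]
    if rejected:
        report = "; ".join(f"line {ln}: {msg}" for ln, msg in rejected)
        warnings.warn(f"rejected {len(rejected)} row(s): {report}")
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model fitting and comparison

def _fit_one(spec, table, settings):
    fit_res = inference.fit(spec, table, settings)
    ll = inference.pointwise_loglik(fit_res)
    loo_res = loo.psis_loo(ll)
    r2 = loo.loo_r2(fit_res, pointwise=ll)
    return fit_res, loo_res, r2


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage and return the report object."""
    config.validate()
    t0 = time.time()
    if config.dataset_path is not None:
        table = ingest_dataset(config.dataset_path)
        logger.info("ingested %d focal rows from %s", len(table), config.dataset_path)
    else:
        observations, roster, agonistic, grooming, landscape, _ = simulate_input_data(
            config
        )
        derived = derive_tables(observations, roster, agonistic, grooming, landscape)
        table = derived["table"]
        logger.info(
            "simulated %d focals over %d individuals (%.1fs)",
            len(table),
            roster.n,
            time.time() - t0,
        )

    tables: dict[str, pd.DataFrame] = {}
    diag_rows = []
    khat_summary: dict[str, dict] = {}
    failures: list[tuple[str, int, str]] = []
    for response in config.responses:
        specs = [
            s
            for s in models.build_model_set(response)
            if s.model_id in config.model_ids
        ]
        fits, loos, r2s, fitted_ids = [], [], [], []
        for spec in specs:
            t_fit = time.time()
            seed = _child_seed(config.seed, 10, spec.model_id,
                               0 if response == "frequency" else 1)
            try:
                missing = [
                    t for t in spec.resolved_terms() if t not in table.columns
                ]
                if missing:
                    raise ValueError(f"missing columns {missing}")
                fit_res, loo_res, r2 = _fit_one(
                    spec, table, config.fit_settings(seed)
                )
            except Exception as exc:
                warnings.warn(
                    f"model {spec.model_id} ({response}) failed and is excluded: {exc}"
                )
                failures.append((response, spec.model_id, str(exc)))
                continue
            fits.append(fit_res)
            loos.append(loo_res)
            r2s.append(r2)
            fitted_ids.append(spec.model_id)
            khat_summary[f"{response}_model_{spec.model_id}"] = loo_res.khat_bands()
            logger.info(
                "fitted model %d (%s) in %.1fs: elpd %.1f, max R-hat %.2f",
                spec.model_id, response, time.time() - t_fit,
                loo_res.elpd, float(fit_res.diagnostics["rhat"].max()),
            )
            diag_rows.append(
                {
                    "response": response,
                    "model_id": spec.model_id,
                    "max_rhat": float(fit_res.diagnostics["rhat"].max()),
                    "min_ess": float(fit_res.diagnostics["ess"].min()),
                    "accept_rate": fit_res.accept_rate,
                    "n_bad_k": loo_res.n_bad_k(),
                    "elpd": loo_res.elpd,
                    "elpd_se": loo_res.se,
                    "seconds": round(time.time() - t_fit, 2),
                }
            )
        if not fitted_ids:
            raise RuntimeError(f"every model failed for response {response!r}")
        stack = stacking.stacking_weights(
            loos, model_ids=fitted_ids, seed=_child_seed(config.seed, 20)
        )
        stack = stacking.restack(
            stack, loos, threshold=config.stacking_threshold,
            seed=_child_seed(config.seed, 21),
        )
        tables[response] = _stack_table(response, specs, fitted_ids, stack, r2s)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    return PipelineReport(
        tables=tables,
        diagnostics=pd.DataFrame(diag_rows),
        failures=failures,
        config=config,
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        seed=config.seed,
        khat_summary=khat_summary,
    )


def _stack_table(response, specs, fitted_ids, stack, r2s) -> pd.DataFrame:
    label_of = {s.model_id: s.label for s in specs}
    rows = []
    for k, model_id in enumerate(fitted_ids):
        r2 = r2s[k]
        w = stack.weight_of(model_id)
        sw = stack.restacked_weight_of(model_id)
        rows.append(
            {
                "model_id": model_id,
                "label": label_of[model_id],
                "response": response,
                "weight": w,
                "shared_weight": sw,
                "accurate": bool(w >= stacking.ACCURACY_FLAG_THRESHOLD),
                "marginal_r2": r2.marginal,
                "marginal_r2_low": r2.marginal_interval[0],
                "marginal_r2_high": r2.marginal_interval[1],
                "conditional_r2": r2.conditional,
                "conditional_r2_low": r2.conditional_interval[0],
                "conditional_r2_high": r2.conditional_interval[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering

def _fmt(x: float) -> str:
    return f"{x:.3f}"


def render_report(report: PipelineReport, output_dir: str | Path | None = None) -> dict:
    """Write CSV and markdown stacking tables (3-decimal weights) plus provenance."""
    outdir = Path(output_dir or report.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for response, table in report.tables.items():
        csv_path = outdir / f"stacking_{response}.csv"
        md_path = outdir / f"stacking_{response}.md"
        disp = pd.DataFrame(
            {
                "model_id": table["model_id"],
                "label": table["label"],
                "weight": table["weight"].map(_fmt),
                "shared_weight": table["shared_weight"].map(_fmt),
                "accurate": table["accurate"].map(lambda b: "yes" if b else "no"),
                "marginal_r2": [
                    f"{_fmt(m)} ({_fmt(lo)}, {_fmt(hi)})"
                    for m, lo, hi in zip(
                        table["marginal_r2"],
                        table["marginal_r2_low"],
                        table["marginal_r2_high"],
                    )
                ],
                "conditional_r2": [
                    f"{_fmt(m)} ({_fmt(lo)}, {_fmt(hi)})"
                    for m, lo, hi in zip(
                        table["conditional_r2"],
                        table["conditional_r2_low"],
                        table["conditional_r2_high"],
                    )
                ],
            }
        )
        disp.to_csv(csv_path, index=False)
        lines = [
            f"# Stacking weights and LOO Bayesian R2 - {response} of looking bouts",
            "",
            "| Model | Hypothesis | Weights | Shared weights | Accurate (w >= 0.1) | Marginal R2 | Conditional R2 |",
            "|---|---|---|---|---|---|---|",
        ]
        for _, row in disp.iterrows():
            lines.append(
                f"| {row['model_id']} | {row['label']} | {row['weight']} | "
                f"{row['shared_weight']} | {row['accurate']} | "
                f"{row['marginal_r2']} | {row['conditional_r2']} |"
            )
        md_path.write_text("\n".join(lines) + "\n")
        written[response] = (csv_path, md_path)

    report.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)
    (outdir / "loo_khat.json").write_text(
        json.dumps(report.khat_summary, indent=2, sort_keys=True)
    )
    provenance = {
        "config": report.config.to_dict(),
        "config_hash": report.config_hash,
        "seed": report.seed,
        "failures": report.failures,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(report.config.to_dict(), fh, sort_keys=True)
    return written
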