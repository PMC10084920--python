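"""End-to-end orchestration: cohort -> scoring -> DNB -> deconvolution ->
TF model -> fixture statistics, with one global seed fanned out to modules.

Seed scheme: the RNG seed of module ``m`` is ``SeedSequence([global_seed,
MODULE_OFFSETS[m]])`` reduced to a 31-bit integer, so changing one module's
seed (via its config block) leaves every other module's output unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import deconv, dnb, fixtures, genomics, scoring, synthetic, tfmodel

logger = logging.getLogger("luas")

MODULE_OFFSETS = {"cohort": 1, "dnb": 2, "tfmodel": 3, "deconv": 4, "genomics": 5}


def module_seed(global_seed: int, module: str) -> int:
    """31-bit per-module seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), MODULE_OFFSETS[module]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated pipeline configuration. Unknown keys are rejected."""

    seed: int = 0
    outdir: str = "luas_run"
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    dnb: dict = field(default_factory=dict)  # DNBParams overrides
    tfmodel: dict = field(default_factory=dict)  # TFParams overrides + scan/sim sizes
    landscape: bool = True

    _TF_EXTRA = {"alpha_s_grid_points", "n_traj", "T", "grid_shape"}

    def __post_init__(self) -> None:
        _check_keys(self.cohort, {f.name for f in dataclasses.fields(synthetic.CohortConfig)} - {"seed"}, "cohort")
        _check_keys(self.dnb, {f.name for f in dataclasses.fields(dnb.DNBParams)}, "dnb")
        tf_fields = {f.name for f in dataclasses.fields(tfmodel.TFParams)} | self._TF_EXTRA
        _check_keys(self.tfmodel, tf_fields, "tfmodel")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("run config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        _check_keys(raw, known, "run config")
        return cls(**raw)


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the report dict and
    writes report.json / report.md plus stage TSVs under cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "parameters": {}}

    # ---- cohort ------------------------------------------------------
    cohort_cfg = synthetic.CohortConfig(seed=module_seed(cfg.seed, "cohort"), **cfg.cohort)
    logger.info("cohort: %s", cohort_cfg)
    report["parameters"]["cohort"] = cohort_cfg.to_dict()
    expr = synthetic.gen_expression_cohort(cohort_cfg)

    # ---- scoring / ranking / subtypes --------------------------------
    sets = [
        scoring.GeneSet("adeno_markers", frozenset(expr.genes_with_role("adeno_marker")), "adeno"),
        scoring.GeneSet("squam_markers", frozenset(expr.genes_with_role("squam_marker")), "squamous"),
        scoring.GeneSet("immune_cells", frozenset(expr.genes_with_role("immune")), "immune"),
    ]
    scores = scoring.score_gene_sets(expr, sets)
    ranking = scoring.rank_samples(scores, "squam_markers")
    subtypes = scoring.assign_subtype(scores, "adeno_markers", "squam_markers", "immune_cells")
    counts = subtypes.value_counts().to_dict()
    report["subtype_counts"] = {k: int(v) for k, v in sorted(counts.items())}

    # ---- DNB ----------------------------------------------------------
    dnb_params = dnb.DNBParams(**cfg.dnb)
    report["parameters"]["dnb"] = dataclasses.asdict(dnb_params)
    trace = dnb.sliding_dnb(expr, ranking.order, dnb_params)
    trace.to_tsv(outdir / "dnb_trace.tsv")
    tip = trace.tipping_window
    tip_mod = trace.tipping_module
    report["dnb"] = {
        "n_windows": int(len(trace.table)),
        "tipping_window": None if tip is None else int(tip),
        "tipping_module_size": 0 if tip_mod is None else len(tip_mod.genes),
        "max_CI": float(trace.table["CI"].max()),
        "median_CI": float(trace.table["CI"].median()),
    }
    if tip_mod is not None:
        (outdir / "dnb_module.json").write_text(
            json.dumps({"window": tip, "genes": list(tip_mod.genes)}, indent=2)
        )

    # ---- deconvolution ------------------------------------------------
    labels = subtypes.map({"TRU-like": "adeno", "basal-like": "squam"}).dropna()
    sig = deconv.build_signature_matrix(expr, labels=labels)
    frac = deconv.estimate_fractions(expr, sig)
    frac.fractions.to_csv(outdir / "deconvolution.tsv", sep="\t", index_label="sample")
    corr = deconv.correlate_fractions(frac, scores, ["immune_cells"])
    report["deconvolution"] = {
        "mean_f_adeno": float(frac.fractions["f_adeno"].mean()),
        "immune_correlations": corr.to_dict(orient="records"),
    }

    # ---- TF model -----------------------------------------------------
    tf_overrides = {k: v for k, v in cfg.tfmodel.items() if k not in RunConfig._TF_EXTRA}
    theta = tfmodel.TFParams(**tf_overrides)
    report["parameters"]["tfmodel"] = dataclasses.asdict(theta)
    n_grid = int(cfg.tfmodel.get("alpha_s_grid_points", 21))
    grid = np.linspace(0.0, 2.0 * theta.alpha_A, n_grid)
    diagram = tfmodel.bifurcation_scan(theta, grid, n_starts=60)
    report["bifurcation"] = {
        "regime_sequence": diagram.regime_sequence(),
        "boundaries": diagram.bifurcation_values(),
    }
    if cfg.landscape:
        fps = tfmodel.find_fixed_points(theta, n_starts=80)
        stable = [np.array(fp.x) for fp in fps if fp.stable and abs(fp.u) > tfmodel.U_TOL]
        if stable:
            n_traj = int(cfg.tfmodel.get("n_traj", 40))
            T = float(cfg.tfmodel.get("T", 200.0))
            starts = np.vstack([stable[i % len(stable)] for i in range(n_traj)])
            ens = tfmodel.simulate_sde(
                theta, starts, T=T, n_traj=n_traj, seed=module_seed(cfg.seed, "tfmodel")
            )
            grid_shape = tuple(cfg.tfmodel.get("grid_shape", (40, 40)))
            land = tfmodel.estimate_landscape(ens, grid_shape=grid_shape)
            u_min, v_min = land.global_minimum()
            report["landscape"] = {
                "global_minimum_u": u_min,
                "global_minimum_v": v_min,
                "n_minima": len(land.minima()),
            }

    # ---- fixture contingency percentages ------------------------------
    fixture_stats = []
    for name, num, den, dec in [
        ("nsclc_collection", "LUAS", "NSCLC", 1),
        ("cohort_stage", "stage_I", "total", 1),
        ("smoking", "non_smoker", "total", 1),
        ("egfr_alleles", "L858R", "EGFR_mutant", 0),
        ("egfr_alleles", "ex19del", "EGFR_mutant", 0),
        ("erbb2_alleles", "ex20ins", "ERBB2_mutant", 0),
        ("alk_fusion", "ALK_fusion", "rnaseq_samples", 0),
        ("alk_in_C1", "in_C1", "ALK_fusion", 1),
        ("eml4_alk_mouse", "AST_positive", "mice", 0),
    ]:
        fx = fixtures.load_fixture(name)
        fixture_stats.append(
            {
                "fixture": name,
                "numerator": num,
                "denominator": den,
                "percent": genomics.contingency_percent(fx, num, den, dec),
                "provenance": fx.provenance,
            }
        )
    report["fixture_percentages"] = fixture_stats

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    lines = ["# LUAS pipeline report", ""]
    lines.append(f"Global seed: {report['seed']}")
    lines.append("")
    lines.append("## Subtype counts")
    for k, v in report.get("subtype_counts", {}).items():
        lines.append(f"- {k}: {v}")
    d = report.get("dnb", {})
    lines += [
        "",
        "## DNB",
        f"- tipping window: {d.get('tipping_window')}",
        f"- module size: {d.get('tipping_module_size')}",
        f"- max CI: {d.get('max_CI'):.3f} (median {d.get('median_CI'):.3f})",
    ]
    b = report.get("bifurcation", {})
    lines += [
        "",
        "## TF model",
        f"- regime sequence: {' -> '.join(b.get('regime_sequence', []))}",
        f"- bifurcation values: {b.get('boundaries')}",
    ]
    lines += ["", "## Fixture percentages"]
    for row in report.get("fixture_percentages", []):
        lines.append(
            f"- {row['fixture']} {row['numerator']}/{row['denominator']}: {row['percent']}%"
        )
    return "\n".join(lines) + "\n"
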