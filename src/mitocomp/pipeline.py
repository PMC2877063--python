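"""End-to-end orchestration: config validation, stage execution, reports.

A run is described by a YAML config with one block per stage.  Outputs are
tab-separated tables with ``#``-prefixed provenance headers (inputs,
parameters, seed, version), so a report is a complete record of how it was
produced.  All randomness flows from the single config seed; rerunning the
same config reproduces deterministic stages bit for bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clock import Calibration, ClockModel, run_mcmc, summarize
from .codonmodel import CodonAlignment
from .compstats import codon_usage, composition, sliding_profile
from .divergence import (
    brower_age,
    count_variation,
    global_align,
    ng86_dnds,
    percent_identity,
)
from .genome import (
    ValidationError,
    extract_gene,
    read_fasta,
    read_feature_table,
    write_fasta,
    write_feature_table,
)
from .selection import fit_site_model, fit_m0, lrt
from .simulate import (
    ClockSimSpec,
    CodonSimSpec,
    MitoSimSpec,
    mutate_genotype_pair,
    simulate_clock_alignment,
    simulate_codon_alignment,
    simulate_mitogenome,
)
from .trees import PhyloTree

STAGES = ("simulate", "stats", "compare", "selection", "date")


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    stages: list[str]
    params: dict
    source_path: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except OSError as exc:
            raise ValidationError(f"cannot read config: {exc}") from exc
        diags = validate_config_dict(raw)
        errors = [d for d in diags if d.startswith("error")]
        if errors:
            raise ValidationError("; ".join(errors))
        return cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw.get("output_dir", "mitocomp_out")),
            stages=list(raw.get("stages", ["simulate", "stats"])),
            params={k: v for k, v in raw.items() if k in STAGES},
            source_path=path,
        )


def validate_config(path: str | Path) -> list[str]:
    """All schema diagnostics for a config file, reported at once."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        return [f"error: unreadable config: {exc}"]
    except yaml.YAMLError as exc:
        return [f"error: invalid YAML: {exc}"]
    return validate_config_dict(raw)


def validate_config_dict(raw) -> list[str]:
    diags: list[str] = []
    if not isinstance(raw, dict):
        return ["error: config must be a mapping"]
    if "seed" not in raw:
        diags.append("error: missing required key 'seed'")
    else:
        try:
            if int(raw["seed"]) < 0:
                diags.append("error: seed must be a non-negative integer")
        except (TypeError, ValueError):
            diags.append("error: seed must be an integer")
    stages = raw.get("stages", [])
    for s in stages:
        if s not in STAGES:
            diags.append(f"error: unknown stage {s!r}")
    if "date" in stages:
        date_cfg = raw.get("date", {}) or {}
        if not date_cfg.get("tree") and not date_cfg.get("simulate", True):
            diags.append("error: 'date' stage needs a tree (or simulate: true)")
        gens = date_cfg.get("generations", 200_000)
        if gens < 1_000_000:
            diags.append(
                f"warning: chain length {gens} is a scaled-down desk setting"
            )
    if "selection" in stages:
        sel_cfg = raw.get("selection", {}) or {}
        if sel_cfg.get("alignment") and not sel_cfg.get("tree"):
            diags.append("error: 'selection' with an alignment needs a tree")
    for stage in STAGES:
        block = raw.get(stage)
        if block is not None and not isinstance(block, dict):
            diags.append(f"error: stage block {stage!r} must be a mapping")
    return diags


@dataclass
class ReportBundle:
    """Paths of every table the run produced, plus failures if any."""

    output_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _provenance(config: RunConfig, stage: str, params: dict) -> str:
    lines = [
        f"# mitocomp {__version__}",
        f"# stage: {stage}",
        f"# seed: {config.seed}",
    ]
    if config.source_path:
        lines.append(f"# config: {config.source_path}")
    for k, v in sorted(params.items()):
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    path.write_text(header + buf.getvalue())


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages in dependency order.

    Stage failures are captured per stage; completed outputs are never
    rewritten by a later failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out)
    ctx: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        params = config.params.get(stage) or {}
        try:
            _STAGE_FUNCS[stage](config, params, ctx, bundle)
        except Exception as exc:  # pragma: no cover - failure manifest path
            bundle.failures[stage] = str(exc)
    if bundle.failures:
        manifest = out / "failures.txt"
        manifest.write_text(
            "\n".join(f"{k}: {v}" for k, v in bundle.failures.items()) + "\n"
        )
    return bundle


def _load_or_simulate_genomes(config, params, ctx):
    if "genomes" in ctx:
        return ctx["genomes"], ctx["tables"]
    if params.get("genome"):
        genomes = read_fasta(params["genome"])
        table = read_feature_table(params["features"])
        ctx["genomes"] = genomes
        ctx["tables"] = [table] * len(genomes)
    else:
        spec = MitoSimSpec(seed=config.seed)
        g1, t1 = simulate_mitogenome(spec)
        g2, t2 = mutate_genotype_pair(g1, t1, seed=config.seed + 1)
        ctx["genomes"] = [g1, g2]
        ctx["tables"] = [t1, t2]
    return ctx["genomes"], ctx["tables"]


def _stage_simulate(config, params, ctx, bundle):
    spec = MitoSimSpec(
        seed=config.seed,
        at_fraction=params.get("at_fraction", 0.78),
        cr_at_fraction=params.get("cr_at_fraction", 0.936),
        t_stretch_length=params.get("t_stretch_length", 17),
    )
    g1, t1 = simulate_mitogenome(spec)
    g2, t2 = mutate_genotype_pair(
        g1,
        t1,
        n_cds_subs=params.get("n_cds_subs", 10),
        n_cr_subs=params.get("n_cr_subs", 6),
        n_cr_indels=params.get("n_cr_indels", 9),
        seed=config.seed + 1,
    )
    ctx["genomes"] = [g1, g2]
    ctx["tables"] = [t1, t2]
    out = bundle.output_dir
    write_fasta([g1, g2], out / "genomes.fasta")
    prov = _provenance(config, "simulate", params)
    write_feature_table(t1, out / "features_a.tsv", provenance=prov)
    write_feature_table(t2, out / "features_b.tsv", provenance=prov)
    truth = pd.DataFrame(
        [
            ("at_fraction", spec.at_fraction),
            ("cr_at_fraction", spec.cr_at_fraction),
            ("t_stretch_length", spec.t_stretch_length),
            ("n_cds_subs", params.get("n_cds_subs", 10)),
            ("n_cr_subs", params.get("n_cr_subs", 6)),
            ("n_cr_indels", params.get("n_cr_indels", 9)),
        ],
        columns=["parameter", "value"],
    )
    path = out / "simulation_truth.tsv"
    _write_table(truth, path, _provenance(config, "simulate", params))
    bundle.tables["simulation_truth"] = path
    for name in ("genomes.fasta", "features_a.tsv", "features_b.tsv"):
        bundle.tables[name.split(".")[0]] = out / name


def _stage_stats(config, params, ctx, bundle):
    genomes, tables = _load_or_simulate_genomes(config, params, ctx)
    rows = []
    for g in genomes:
        prof = composition(g.sequence)
        rep = prof.reported()
        rows.append(
            {
                "genome": g.id,
                "total_nt": prof.total,
                "A": prof.a,
                "C": prof.c,
                "G": prof.g,
                "T": prof.t,
                "AT_percent": rep["at_percent"],
                "G_skew": rep["g_skew"],
                "T_skew": rep["t_skew"],
            }
        )
    comp_df = pd.DataFrame(rows)
    out = bundle.output_dir
    path = out / "composition.tsv"
    _write_table(comp_df, path, _provenance(config, "stats", params))
    bundle.tables["composition"] = path

    usage_rows = []
    for g, t in zip(genomes, tables):
        usage = codon_usage(g, t)
        vals = usage.rscu
        for codon in sorted(usage.counts):
            usage_rows.append(
                {
                    "genome": g.id,
                    "codon": codon,
                    "count": usage.counts[codon],
                    "rscu": vals.get(codon),
                }
            )
    path = out / "codon_usage.tsv"
    _write_table(
        pd.DataFrame(usage_rows), path, _provenance(config, "stats", params)
    )
    bundle.tables["codon_usage"] = path

    window = params.get("window", 500)
    step = params.get("step", 250)
    prof_rows = [
        {"midpoint": m, "AT_percent": a, "GC_percent": gc}
        for m, a, gc in sliding_profile(genomes[0], window, step)
    ]
    path = out / "sliding_profile.tsv"
    _write_table(
        pd.DataFrame(prof_rows), path, _provenance(config, "stats", params)
    )
    bundle.tables["sliding_profile"] = path


def _stage_compare(config, params, ctx, bundle):
    genomes, tables = _load_or_simulate_genomes(config, params, ctx)
    if len(genomes) < 2:
        raise ValidationError("compare stage needs two genomes")
    g1, g2 = genomes[0], genomes[1]
    t1, t2 = tables[0], tables[1]
    rows = []
    for f1 in t1:
        try:
            f2 = t2.get(f1.name)
        except KeyError:
            continue
        s1 = extract_gene(g1, f1)
        s2 = extract_gene(g2, f2)
        aln = global_align(s1, s2)
        ident = percent_identity(aln, reported=True)
        var, subs, indels = count_variation(aln)
        row = {
            "gene": f1.name,
            "identity_pct": ident,
            "variable_sites": var,
            "substitutions": subs,
            "indel_events": indels,
            "brower_age_my": round(brower_age(100.0 - ident), 4),
        }
        if f1.kind.value == "PCG":
            trail = len(f1.stop_codon) if f1.incomplete_stop else 0
            c1, c2 = s1[: len(s1) - trail], s2[: len(s2) - trail]
            if len(c1) == len(c2) and len(c1) % 3 == 0:
                res = ng86_dnds(c1, c2)
                row.update(
                    {
                        "dN": None if res.dN is None else round(res.dN, 6),
                        "dS": None if res.dS is None else round(res.dS, 6),
                        "omega": None if res.omega is None else round(res.omega, 4),
                    }
                )
        rows.append(row)
    path = bundle.output_dir / "pairwise_divergence.tsv"
    _write_table(pd.DataFrame(rows), path, _provenance(config, "compare", params))
    bundle.tables["pairwise_divergence"] = path


_DEFAULT_SELECTION_TREE = "((A:0.06,B:0.06):0.03,(C:0.06,D:0.06):0.03);"


def _stage_selection(config, params, ctx, bundle):
    models = params.get("models", ["M0", "M1a", "M2a", "M7", "M8"])
    if params.get("alignment"):
        genomes = read_fasta(params["alignment"])
        seqs = {g.id: g.sequence for g in genomes}
        aln = CodonAlignment.from_sequences(seqs)
        tree = PhyloTree.read(params["tree"])
    else:
        tree = PhyloTree.from_newick(
            params.get("tree_newick", _DEFAULT_SELECTION_TREE)
        )
        spec = CodonSimSpec(
            seed=config.seed,
            tree=tree,
            kappa=params.get("kappa", 2.0),
            site_classes=tuple(
                tuple(c) for c in params.get("site_classes", [[1.0, 0.1]])
            ),
            n_codons=params.get("n_codons", 500),
        )
        aln = simulate_codon_alignment(spec)
    n_starts = params.get("n_starts", 1)
    m0 = fit_m0(aln, tree, n_starts=n_starts, seed=config.seed)
    fits = {"M0": m0}
    for model in models:
        if model == "M0":
            continue
        fits[model] = fit_site_model(
            aln, tree, model, m0=m0, n_starts=n_starts, seed=config.seed
        )
    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "model": name,
                "lnL": round(fit.lnL, 4),
                "kappa": round(fit.kappa, 4),
                "omega_classes": "; ".join(
                    f"p={p:.4f}, w={w:.4f}" for p, w in fit.omega_classes
                ),
                "beta_p": fit.beta_p,
                "beta_q": fit.beta_q,
                "n_params": fit.n_params,
            }
        )
    path = bundle.output_dir / "site_models.tsv"
    _write_table(pd.DataFrame(rows), path, _provenance(config, "selection", params))
    bundle.tables["site_models"] = path

    lrt_rows = []
    for null, alt in (("M1a", "M2a"), ("M7", "M8")):
        if null in fits and alt in fits:
            r = lrt(fits[null], fits[alt])
            lrt_rows.append(
                {
                    "null": null,
                    "alt": alt,
                    "statistic": round(r.statistic, 4),
                    "df": r.df,
                    "p_value": round(r.p_value, 4),
                }
            )
    if lrt_rows:
        path = bundle.output_dir / "lrt.tsv"
        _write_table(
            pd.DataFrame(lrt_rows), path, _provenance(config, "selection", params)
        )
        bundle.tables["lrt"] = path
    ctx["selection_fits"] = fits


_DEFAULT_TIME_TREE = "((A:40,B:40):60,(C:70,D:70):30);"


def _stage_date(config, params, ctx, bundle):
    if params.get("alignment"):
        genomes = read_fasta(params["alignment"])
        alignment = {g.id: g.sequence for g in genomes}
        tree = PhyloTree.read(params["tree"], rooted=True)
    else:
        tree = PhyloTree.from_newick(
            params.get("tree_newick", _DEFAULT_TIME_TREE), rooted=True
        )
        spec = ClockSimSpec(
            seed=config.seed,
            time_tree=tree,
            clock="strict",
            mean_rate=params.get("true_rate", 0.01),
            n_sites=params.get("n_sites", 1000),
        )
        alignment = simulate_clock_alignment(spec).alignment
    clock = ClockModel(
        kind=params.get("clock", "strict"),
        rate_prior_mean=params.get("rate_prior_mean", 0.01),
        rate_prior_sd=params.get("rate_prior_sd", 0.005),
    )
    cal_specs = params.get("calibrations")
    if cal_specs:
        calibrations = [
            Calibration.of(tuple(c["taxa"]), c["mean"], c.get("sd")) for c in cal_specs
        ]
    else:
        calibrations = [Calibration.of(tuple(tree.taxa), 100.0, 5.0)]
    trace = run_mcmc(
        alignment,
        tree,
        clock,
        calibrations,
        generations=params.get("generations", 20_000),
        thinning=params.get("thinning", 20),
        seed=config.seed,
    )
    summ = summarize(trace)
    rows = [
        {
            "node": node,
            "mean_age_my": round(summ.mean_age[node], 3),
            "hpd95_low": round(summ.hpd95[node][0], 3),
            "hpd95_high": round(summ.hpd95[node][1], 3),
            "ess": round(summ.ess[f"age_{node}"], 1),
        }
        for node in summ.mean_age
    ]
    path = bundle.output_dir / "node_ages.tsv"
    _write_table(pd.DataFrame(rows), path, _provenance(config, "date", params))
    bundle.tables["node_ages"] = path
    trace_path = bundle.output_dir / "trace.tsv"
    _write_table(
        trace.samples.reset_index(), trace_path, _provenance(config, "date", params)
    )
    bundle.tables["trace"] = trace_path


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "stats": _stage_stats,
    "compare": _stage_compare,
    "selection": _stage_selection,
    "date": _stage_date,
}
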