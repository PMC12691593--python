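"""End-to-end orchestration: io -> filters -> rates -> spectrum -> bias ->
popgen -> neutrality tests -> positional bias, with a JSON-serializable report.

Every number in the report is the direct output of one estimator call;
provenance (config hash, seed, version) travels with it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .bias import summarize_bias
from .design import ExperimentDesign
from .genome import bin_genome, load_genome
from .neutrality import (
    binned_rates,
    coding_enrichment_test,
    dispersion_test,
    origin_distance_correlation,
)
from .popgen import (
    drift_barrier_regression,
    effective_population_size,
    nucleotide_diversity,
    read_alignment,
)
from .rates import indel_length_summary, species_rate, spectrum
from .variants import (
    apply_hard_filters,
    cluster_complex,
    read_mutation_table,
    subtract_ancestral,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]

ALL_STAGES = ("rates", "spectrum", "bias", "popgen", "tests", "positional")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _rate_dict(est, design=None):
    d = {
        "mean_rate": est.mean_rate,
        "se": est.se,
        "ci95_low": est.ci95_low,
        "ci95_high": est.ci95_high,
        "m_total": est.m_total,
        "n_sites": est.n_sites,
    }
    return d


def run_pipeline(config: dict, seed: int | None = None, stages=ALL_STAGES) -> dict:
    """Run the analysis described by ``config`` and return the report dict.

    Config keys (paths are relative to the caller's cwd):

    - ``genome``: {``fasta``, ``origin``, ``coding_bed``?}
    - ``mutations``: path to the TSV mutation table
    - ``design``: {``species``, ``n_lines``, ``n_transfers``, ``generations_total``}
    - ``ancestral_variants``?: list of [position, ref, alt]
    - ``hard_filters``?: true to apply the default thresholds
    - ``complex_window``?: bp (default 50)
    - ``alpha_obs``?: observed genome-wide AT fraction (default from genome)
    - ``alignment``?: codon-alignment FASTA for diversity/Ne
    - ``comparative_table``?: TSV with species, ne, rate for the scaling fit
    - ``bins``?: {``fixed_count``} or {``fixed_width``} (default fixed_count 25)
    - ``n_tests``?: Bonferroni multiplier for positional tests (default 6)
    """
    report: dict = {"provenance": _provenance(config, seed)}

    def run_stage(name, fn):
        if name not in stages and name != "io":
            return
        try:
            fn()
        except Exception as err:  # noqa: BLE001 - stage name travels with cause
            raise PipelineError(name, err) from err

    state: dict = {}

    def stage_io():
        g = config["genome"]
        fasta = Path(g["fasta"])
        if not fasta.exists():
            raise FileNotFoundError(f"genome FASTA not found: {fasta}")
        profile = load_genome(fasta, origin=int(g.get("origin", 1)),
                              intervals_path=g.get("coding_bed"))
        mpath = Path(config["mutations"])
        if not mpath.exists():
            raise FileNotFoundError(f"mutation table not found: {mpath}")
        callsets = read_mutation_table(mpath)
        if config.get("hard_filters"):
            thresholds = None if config["hard_filters"] is True else config["hard_filters"]
            callsets = [apply_hard_filters(cs, thresholds) for cs in callsets]
        ancestral = [(int(p), r, a) for p, r, a in config.get("ancestral_variants", [])]
        if ancestral:
            callsets = [subtract_ancestral(cs, ancestral) for cs in callsets]
        callsets = [cluster_complex(cs, int(config.get("complex_window", 50))) for cs in callsets]
        d = config["design"]
        design = ExperimentDesign(
            species=d.get("species", "unknown"),
            n_lines=int(d["n_lines"]),
            n_transfers=int(d.get("n_transfers", 0)),
            generations_total=float(d["generations_total"]),
            genome=profile,
        )
        # pad lines that had zero calls
        seen = {cs.line_id for cs in callsets}
        from .variants import LineCallSet

        for i in range(design.n_lines - len(callsets)):
            pad_id = f"_empty{i:03d}"
            while pad_id in seen:
                pad_id += "x"
            callsets.append(LineCallSet(pad_id))
        state.update(profile=profile, callsets=callsets, design=design)

    def stage_rates():
        design, callsets, profile = state["design"], state["callsets"], state["profile"]
        out = {}
        for label, attr in (("SNM", "snms"), ("insertion", "insertions"),
                            ("deletion", "deletions"), ("complex", "complexes")):
            counts = {cs.line_id: len(getattr(cs, attr)) for cs in callsets}
            out[label] = _rate_dict(species_rate(design, counts, n_sites=profile.length))
        out["indel_lengths"] = indel_length_summary(callsets)
        report["rates"] = out

    def stage_spectrum():
        table = spectrum(state["callsets"], state["profile"], state["design"])
        state["spectrum"] = table
        report["spectrum"] = table.to_records()

    def stage_bias():
        profile = state["profile"]
        alpha_obs = config.get("alpha_obs", 1.0 - profile.gc_fraction)
        report["bias"] = _jsonable(summarize_bias(state["spectrum"], alpha_obs=alpha_obs))

    def stage_popgen():
        out = {}
        if config.get("alignment"):
            aln = read_alignment(config["alignment"])
            pi = nucleotide_diversity(aln)
            mu = report.get("rates", {}).get("SNM", {}).get("mean_rate")
            out["pi_fourfold"] = pi
            if mu:
                out["ne"] = effective_population_size(pi, mu)
                out["mu"] = mu
        if config.get("comparative_table"):
            table = pd.read_csv(config["comparative_table"], sep="\t")
            fit = drift_barrier_regression(table, focal_species=config.get("focal_species", ()))
            out["drift_barrier"] = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_value": fit.r_value,
                "predictions": _jsonable(fit.predictions),
            }
        if out:
            report["popgen"] = out

    def stage_tests():
        callsets, profile = state["callsets"], state["profile"]
        out = {}
        for label, attr in (("SNM", "snms"), ("insertion", "insertions"), ("deletion", "deletions")):
            counts = [len(getattr(cs, attr)) for cs in callsets]
            if sum(counts) == 0:
                continue
            res = dispersion_test(counts)
            out[f"dispersion_{label}"] = {
                "distribution": res.distribution, "chi2": res.chi2,
                "df": res.df, "p": res.p,
            }
        if profile.coding_intervals:
            records = [r for cs in callsets for r in cs.records]
            try:
                chi2, p = coding_enrichment_test(records, profile)
                out["coding_enrichment"] = {"chi2": chi2, "p": p}
            except ValueError as err:
                out["coding_enrichment"] = {"error": str(err)}
        report["tests"] = out

    def stage_positional():
        profile, design, callsets = state["profile"], state["design"], state["callsets"]
        scheme = config.get("bins", {"fixed_count": 25})
        bins = bin_genome(profile, **{k: int(v) for k, v in scheme.items()})
        records = [r for cs in callsets for r in cs.records]
        series = binned_rates(records, bins, design)
        corr = origin_distance_correlation(series, n_tests=int(config.get("n_tests", 6)))
        report["positional"] = {
            t: {"rho": c.rho, "p_raw": c.p_raw, "p_bonferroni": c.p_bonferroni,
                "n_bins": c.n_bins}
            for t, c in corr.items()
        }

    run_stage("io", stage_io)
    run_stage("rates", stage_rates)
    if "spectrum" in stages or "bias" in stages:
        try:
            stage_spectrum()
        except Exception as err:  # noqa: BLE001
            raise PipelineError("spectrum", err) from err
    run_stage("bias", stage_bias)
    run_stage("popgen", stage_popgen)
    run_stage("tests", stage_tests)
    run_stage("positional", stage_positional)
    return _jsonable(report)


def _provenance(config: dict, seed) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "mutkit_version": __version__,
    }


def write_report(report: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path
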