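"""End-to-end cohort analysis: FASTA in, report bundle out.

Stage order: QC -> per-gene composition / codon metrics / protein indices ->
cohort analyses (neutrality, parity, mutational forces, correlations,
RSCU~GC3 regressions, representation tally, correspondence analysis, codon
clustering) -> serialized bundle.  The run is deterministic given the input
and configuration; genes failing QC are listed, excluded and counted.

Bundle layout (fixed file names so downstream tooling can address them):
per_gene.tsv, rscu_matrix.tsv, cohort.json, ca_coords.tsv,
codon_dendrogram.nwk, qc_report.tsv, run.log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import codon_metrics as cm
from . import composition as comp
from . import evo_analyses as evo
from . import io_qc
from . import protein_indices as pidx
from .reference import ReferenceCodonUsage, load_reference_table

logger = logging.getLogger(__name__)

#: codons singled out for RSCU ~ GC3 regression: the most over- and
#: under-represented codons plus the two codons whose bias composition
#: fails to explain
FOCUS_CODONS = ("CTG", "CTA", "CGT", "AGG")


@dataclass(frozen=True)
class RunConfig:
    input_path: Union[str, Path] = ""
    reference: Union[str, Path] = "human"
    min_len: int = io_qc.DEFAULT_MIN_LEN
    rscu_over: float = cm.RSCU_OVER
    rscu_under: float = cm.RSCU_UNDER
    odds_over: float = cm.ODDS_OVER
    odds_under: float = cm.ODDS_UNDER
    scs_denominator: str = "multi"
    do_ca: bool = True
    do_clustering: bool = True
    do_plots: bool = False
    output_dir: Optional[Union[str, Path]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 3:
            raise ValueError("min_len must be >= 3")
        if not (self.rscu_over > self.rscu_under > 0):
            raise ValueError("need rscu_over > rscu_under > 0")
        if not (self.odds_over > self.odds_under > 0):
            raise ValueError("need odds_over > odds_under > 0")


@dataclass
class CohortResult:
    per_gene: pd.DataFrame
    rscu_matrix: pd.DataFrame
    qc: pd.DataFrame
    analyses: dict
    provenance: dict
    newick: Optional[str] = None
    ca: Optional[evo.CaResult] = None


def per_gene_metrics(
    record: io_qc.CodingSequence, reference: ReferenceCodonUsage,
    scs_denominator: str = "multi",
) -> dict:
    """All per-gene metrics as one flat dict (one row of per_gene.tsv)."""
    counts = cm.count_codons(record)
    pc = comp.positional_composition(record)
    sk = comp.skew_set(record)
    par = comp.parity_coordinates(record)
    p2 = cm.translational_selection_p2(counts)
    dinuc = cm.dinucleotide_odds_ratios(record)
    protein = io_qc.translate(record)
    prot = pidx.protein_indices(protein)

    row: dict = {"id": record.id, "length_nt": record.length_nt, "n_codons": counts.n_codons}
    for b in "ATGC":
        row[f"pct_{b}"] = pc.pct[b]
        for k in (1, 2, 3):
            row[f"pct_{b}{k}"] = pc.pct_pos[b][k]
    row.update(
        gc=pc.gc, gc1=pc.gc1, gc2=pc.gc2, gc3=pc.gc3, gc12=pc.gc12, gc3s=pc.gc3s,
        at_skew=sk.at_skew, gc_skew=sk.gc_skew, purine_skew=sk.purine_skew,
        pyrimidine_skew=sk.pyrimidine_skew, amino_skew=sk.amino_skew,
        keto_skew=sk.keto_skew, at_bias3=par.at_bias3, gc_bias3=par.gc_bias3,
        scs=cm.scaled_chi_square(counts, denominator=scs_denominator),
        cai=cm.cai(counts, reference),
        p2=p2.p2, p2_wwc=p2.wwc, p2_ssu=p2.ssu, p2_wwy=p2.wwy, p2_ssy=p2.ssy,
    )
    for d in cm.DINUCLEOTIDES:
        row[f"odds_{d}"] = dinuc.odds[d]
    row.update(
        gravy=prot.gravy, aroma=prot.aroma, pi=prot.pi,
        instability=prot.instability, aliphatic=prot.aliphatic,
        hydrophobic_frac=prot.hydrophobic_frac, acidic_frac=prot.acidic_frac,
        basic_frac=prot.basic_frac, neutral_frac=prot.neutral_frac,
        length_aa=prot.length_aa,
    )
    return row


def _reg_dict(r: evo.RegressionResult) -> dict:
    return {"slope": r.slope, "intercept": r.intercept, "r": r.r,
            "r2": r.r2, "p": r.p, "n": r.n}


def _correlation_pairs(per_gene: pd.DataFrame) -> list[tuple[str, str]]:
    """The cohort correlation battery: composition/skews/odds vs CUB and CAI."""
    comp_vars = (
        [f"pct_{b}" for b in "ATGC"]
        + [f"pct_{b}{k}" for b in "ATGC" for k in (1, 2, 3)]
        + ["gc", "gc1", "gc2", "gc3", "gc3s"]
    )
    skew_vars = ["at_skew", "gc_skew", "purine_skew", "pyrimidine_skew",
                 "amino_skew", "keto_skew"]
    protein_vars = ["gravy", "aroma", "pi", "instability", "aliphatic",
                    "hydrophobic_frac", "acidic_frac", "basic_frac",
                    "neutral_frac"]
    pairs = [(v, "scs") for v in comp_vars + skew_vars + protein_vars]
    pairs += [(f"odds_{d}", "scs") for d in cm.DINUCLEOTIDES]
    pairs += [(v, "cai") for v in skew_vars]
    pairs += [("gc3", "cai"), ("gc12", "cai"), ("length_aa", "cai"),
              ("scs", "cai"), ("gc12", "gc3")]
    return pairs


def run_pipeline(config: RunConfig) -> CohortResult:
    records = io_qc.read_fasta(config.input_path)
    reports = [io_qc.qc_filter(r, min_len=config.min_len) for r in records]
    qc_table = io_qc.qc_report_table(reports)
    passed = [r for r, rep in zip(records, reports) if rep.passed]
    logger.info("QC: %d/%d sequences passed", len(passed), len(records))
    if not passed:
        raise ValueError("no sequences passed QC")

    reference = load_reference_table(config.reference)

    rows = [
        per_gene_metrics(r, reference, scs_denominator=config.scs_denominator)
        for r in passed
    ]
    per_gene = pd.DataFrame(rows).set_index("id")

    rscu_matrix = pd.DataFrame(
        [cm.rscu(cm.count_codons(r)) for r in passed],
        index=[r.id for r in passed],
    )[list(cm.INFORMATIVE_CODONS)]

    compositions = [comp.positional_composition(r) for r in passed]
    parities = [comp.parity_coordinates(r) for r in passed]

    analyses: dict = {}
    analyses["n_genes_input"] = len(records)
    analyses["n_genes_pass"] = len(passed)

    neutrality = evo.neutrality_analysis(compositions)
    analyses["neutrality"] = {
        **_reg_dict(neutrality.regression),
        "relative_neutrality_pct": neutrality.relative_neutrality_pct,
        "relative_constraint_pct": neutrality.relative_constraint_pct,
        "mutation_selection_ratio": neutrality.mutation_selection_ratio,
    }

    par = evo.parity_summary(parities)
    analyses["parity"] = {
        axis: {"mean": m, "sd": s} for axis, (m, s) in par.items()
    }

    analyses["mutational_forces"] = {
        base: {**_reg_dict(r), "pct_contribution": 100.0 * r.r2}
        for base, r in evo.mutational_force_regressions(compositions).items()
    }

    gc3 = per_gene["gc3"]
    analyses["rscu_gc3_regressions"] = {
        codon: {
            "gc3": _reg_dict(evo.rscu_gc3_regression(codon, rscu_matrix, gc3)),
            "at3": _reg_dict(
                evo.rscu_gc3_regression(codon, rscu_matrix, gc3, predictor="at3")
            ),
        }
        for codon in FOCUS_CODONS
        if rscu_matrix[codon].notna().sum() >= 3
    }

    corr = evo.correlation_battery(per_gene, _correlation_pairs(per_gene))
    analyses["correlations"] = [
        {"x": c.variable_x, "y": c.variable_y, "r": c.r, "p": c.p,
         "n": c.n, "stars": c.stars}
        for c in corr
    ]

    tally = evo.representation_tally(rscu_matrix)
    analyses["representation"] = tally.reset_index().to_dict(orient="records")

    # cohort-level P2: per-gene mean and pooled-count variants
    terms = per_gene[["p2_wwc", "p2_ssu", "p2_wwy", "p2_ssy"]].sum()
    pooled_denom = terms["p2_wwy"] + terms["p2_ssy"]
    analyses["p2"] = {
        "per_gene_mean": float(per_gene["p2"].mean()),
        "pooled": float((terms["p2_wwc"] + terms["p2_ssu"]) / pooled_denom)
        if pooled_denom else math.nan,
        "pct_genes_above_0.5": float(100.0 * (per_gene["p2"] > 0.5).mean()),
    }

    analyses["cai_summary"] = {
        "mean": float(per_gene["cai"].mean()),
        "min": float(per_gene["cai"].min()),
        "max": float(per_gene["cai"].max()),
        "min_gene": str(per_gene["cai"].idxmin()),
        "max_gene": str(per_gene["cai"].idxmax()),
    }

    ca_result = None
    if config.do_ca:
        ca_result = evo.correspondence_analysis(rscu_matrix)
        frac = ca_result.inertia_fraction
        analyses["correspondence_analysis"] = {
            "axis1_inertia_pct": float(100.0 * frac[0]) if len(frac) else math.nan,
            "axis2_inertia_pct": float(100.0 * frac[1]) if len(frac) > 1 else math.nan,
            "n_axes": int(len(frac)),
            "total_inertia": ca_result.total_inertia,
        }

    newick = None
    if config.do_clustering:
        link, labels = evo.codon_clustering(rscu_matrix)
        newick = evo.linkage_to_newick(link, labels)
        analyses["clustering"] = {"n_codons": len(labels)}

    provenance = {
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
        },
        "reference": reference.name,
    }

    result = CohortResult(
        per_gene=per_gene, rscu_matrix=rscu_matrix, qc=qc_table,
        analyses=analyses, provenance=provenance, newick=newick, ca=ca_result,
    )
    if config.output_dir is not None:
        write_bundle(result, config)
    return result


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    return obj


def write_bundle(result: CohortResult, config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_gene.to_csv(out / "per_gene.tsv", sep="\t")
    result.rscu_matrix.to_csv(out / "rscu_matrix.tsv", sep="\t")
    result.qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    payload = {"analyses": result.analyses, "provenance": result.provenance}
    (out / "cohort.json").write_text(
        json.dumps(_json_safe(payload), indent=2) + "\n"
    )
    if result.ca is not None:
        coords = pd.concat(
            [
                result.ca.row_coords.assign(kind="gene"),
                result.ca.col_coords.assign(kind="codon"),
            ]
        )
        coords.to_csv(out / "ca_coords.tsv", sep="\t")
    if result.newick is not None:
        (out / "codon_dendrogram.nwk").write_text(result.newick + "\n")
    with (out / "run.log").open("w") as log:
        log.write(
            f"genes_in={result.analyses['n_genes_input']} "
            f"genes_pass={result.analyses['n_genes_pass']}\n"
        )
    if config.do_plots:
        _diagnostic_plots(result, out)
    return out


def _diagnostic_plots(result: CohortResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pg = result.per_gene
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pg["gc3"], pg["gc12"], s=15)
    n = result.analyses["neutrality"]
    xs = np.linspace(pg["gc3"].min(), pg["gc3"].max(), 10)
    ax.plot(xs, n["slope"] * xs + n["intercept"], "r-")
    ax.set_xlabel("%GC3")
    ax.set_ylabel("%GC12")
    ax.set_title(f"Neutrality plot (slope={n['slope']:.3f})")
    fig.tight_layout()
    fig.savefig(out / "neutrality.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pg["gc_bias3"], pg["at_bias3"], s=15)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    ax.set_title("Parity rule 2 plot")
    fig.tight_layout()
    fig.savefig(out / "parity.png", dpi=100)
    plt.close(fig)
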