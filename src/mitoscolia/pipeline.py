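"""Orchestration of the three analysis stages behind one CLI.

Stages: ``features`` (composition table) -> ``rscu`` (codon usage) ->
``order``/``modes`` (gene orders, rearrangement events, cluster modes)
-> ``asr`` (ancestral-state reconstruction of the modes on a tree).
Each stage is independently invokable as a subcommand; ``run`` executes
the stages named in a YAML config and writes a manifest.  All analysis
stages are deterministic; randomness is confined to ``simulate``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .ancestral import CharacterMatrix, MkModel, marginal_reconstruction, select_model
from .composition import composition_table, rscu_matrix
from .gene_order import classify_events, detect_cluster_modes, extract_gene_order
from .genomes import read_genbank, read_newick, write_genbank, write_newick
from .simulate import simulate_clade_study

__all__ = ["RunManifest", "run_pipeline", "asr_report", "cli"]


@dataclass
class RunManifest:
    """What a pipeline run produced: inputs, outputs, warnings."""

    version: str
    config_hash: str
    inputs: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _load_genomes(paths, alias: dict[str, str]):
    genomes = []
    for p in paths:
        for g in read_genbank(p):
            g.id = alias.get(g.id, g.id)
            genomes.append(g)
    return genomes


def _orders_frame(orders) -> pd.DataFrame:
    return pd.DataFrame({"taxon": [o.id for o in orders],
                         "gene_order": [o.to_string() for o in orders]})


def _events_frame(reports) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for gene, event in sorted(rep.events.items()):
            rows.append({"taxon": rep.query_id, "gene": gene, "event": event})
    return pd.DataFrame(rows)


def _modes_frame(orders) -> pd.DataFrame:
    rows = []
    for o in orders:
        c1, c2 = detect_cluster_modes(o)
        rows.append({"taxon": o.id,
                     "cluster1": c1 if c1 != "unknown" else "?",
                     "cluster2": c2 if c2 != "unknown" else "?"})
    return pd.DataFrame(rows)


def asr_report(tree, matrix: CharacterMatrix, seed: int = 0,
               warn=lambda msg: None) -> dict:
    """Fit Mk1 and AsymmMk per character, select by AIC, reconstruct nodes."""
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    report: dict = {}
    for char, alphabet in matrix.characters.items():
        states = matrix.column(char)
        for tip in sorted(tip_labels - set(states)):
            warn(f"taxon {tip} absent from modes table; treated as missing data")
        tips = {t: states.get(t) for t in tip_labels}
        fits = []
        for family in ("Mk1", "AsymmMk"):
            fits.append(MkModel(tree, tips, family=family, alphabet=alphabet).fit(seed=seed))
        chosen = select_model(fits)
        recon = marginal_reconstruction(tree, tips, chosen)
        report[char] = {
            "fits": {f.family: {"rates": list(f.rates), "lnL": f.llf, "aic": f.aic,
                                "at_boundary": f.at_boundary} for f in fits},
            "selected": chosen.family,
            "reconstruction": recon.to_json_dict(),
        }
    return report


def run_pipeline(config: str | Path | dict) -> RunManifest:
    """Execute the configured stages; returns the manifest (also written to disk).

    Config keys: ``genbank`` (list of flat files, required), ``tree``
    (newick, required for the asr stage), ``modes`` (TSV; derived from the
    genomes when omitted), ``out_dir``, ``stages`` (default all),
    ``alias`` (genome id -> tree tip label), ``default_branch_length``.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = yaml.safe_load(text)
    else:
        cfg = dict(config)
        text = yaml.safe_dump(cfg, sort_keys=True)
    stages = list(cfg.get("stages", ["features", "rscu", "order", "modes", "asr"]))
    out_dir = Path(cfg.get("out_dir", "."))
    gb_paths = [Path(p) for p in cfg.get("genbank", [])]
    if not gb_paths:
        raise ValueError("config must name at least one GenBank input")
    for p in gb_paths:
        if not p.exists():
            raise FileNotFoundError(f"missing input {p}")
    tree_path = cfg.get("tree")
    if "asr" in stages and not tree_path:
        raise ValueError("asr stage enabled but no tree given")
    if tree_path and not Path(tree_path).exists():
        raise FileNotFoundError(f"missing input {tree_path}")

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__,
                           config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
                           inputs=[str(p) for p in gb_paths] + ([str(tree_path)] if tree_path else []))
    genomes = _load_genomes(gb_paths, cfg.get("alias", {}) or {})

    def emit(name: str, df: pd.DataFrame):
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        manifest.outputs[name.split(".")[0]] = str(path)

    if "features" in stages:
        df, summary = composition_table(genomes)
        emit("composition.tsv", df)
        (out_dir / "composition_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        manifest.outputs["composition_summary"] = str(out_dir / "composition_summary.json")
    if "rscu" in stages:
        emit("rscu.tsv", rscu_matrix(genomes, pooled=True).reset_index())
    orders = None
    if {"order", "modes", "asr"} & set(stages):
        orders = [extract_gene_order(g) for g in genomes]
    if "order" in stages:
        emit("gene_orders.tsv", _orders_frame(orders))
        emit("events.tsv", _events_frame([classify_events(o) for o in orders]))
    if "modes" in stages or ("asr" in stages and not cfg.get("modes")):
        emit("modes.tsv", _modes_frame(orders))
    if "asr" in stages:
        tree = read_newick(Path(tree_path), default_branch_length=cfg.get("default_branch_length", 1.0))
        modes_path = Path(cfg.get("modes") or (out_dir / "modes.tsv"))
        matrix = CharacterMatrix.from_tsv(
            modes_path,
            alphabets={"cluster1": ("mode1", "mode2"), "cluster2": ("mode3", "mode4")})
        report = asr_report(tree, matrix, warn=manifest.warnings.append)
        path = out_dir / "asr.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest.outputs["asr"] = str(path)

    mpath = out_dir / "manifest.json"
    mpath.write_text(manifest.to_json())
    manifest.outputs["manifest"] = str(mpath)
    return manifest


# --- CLI ----------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def cli():
    """Comparative mitogenomics of Scoliidae: composition, gene order, ASR."""


_gb_arg = click.argument("genbank", nargs=-1, required=True,
                         type=click.Path(exists=True))
_out_opt = click.option("--out-dir", default=".", show_default=True,
                        type=click.Path(file_okay=False))


@cli.command()
@_gb_arg
@_out_opt
def features(genbank, out_dir):
    """Base composition, A+T content and skews per genome."""
    run_pipeline({"genbank": list(genbank), "out_dir": out_dir, "stages": ["features"]})


@cli.command(name="rscu")
@_gb_arg
@_out_opt
def rscu_cmd(genbank, out_dir):
    """Relative synonymous codon usage per genome (plus pooled)."""
    run_pipeline({"genbank": list(genbank), "out_dir": out_dir, "stages": ["rscu"]})


@cli.command()
@_gb_arg
@_out_opt
def order(genbank, out_dir):
    """Signed gene orders and rearrangement events vs the ancestral order."""
    run_pipeline({"genbank": list(genbank), "out_dir": out_dir, "stages": ["order"]})


@cli.command()
@_gb_arg
@_out_opt
def modes(genbank, out_dir):
    """Cluster-1/cluster-2 rearrangement modes per genome."""
    run_pipeline({"genbank": list(genbank), "out_dir": out_dir, "stages": ["modes"]})


@cli.command()
@click.argument("tree", type=click.Path(exists=True))
@click.argument("modes_tsv", type=click.Path(exists=True))
@_out_opt
def asr(tree, modes_tsv, out_dir):
    """Ancestral-state reconstruction of cluster modes on a tree."""
    t = read_newick(Path(tree), default_branch_length=1.0)
    matrix = CharacterMatrix.from_tsv(
        modes_tsv, alphabets={"cluster1": ("mode1", "mode2"),
                              "cluster2": ("mode3", "mode4")})
    report = asr_report(t, matrix, warn=lambda m: click.echo(f"warning: {m}", err=True))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "asr.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    click.echo(str(out / "asr.json"))


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def run(config_path):
    """Run the configured stages end to end."""
    manifest = run_pipeline(config_path)
    click.echo(manifest.to_json())


@cli.command()
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-taxa", default=12, show_default=True, type=int)
@click.option("--target-at", default=0.82, show_default=True, type=float)
@_out_opt
def simulate(seed, n_taxa, target_at, out_dir):
    """Emit a synthetic study: GenBank genomes, a tree, and a modes table."""
    study = simulate_clade_study(n_taxa=n_taxa, seed=seed, target_at=target_at)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genbank(study.genomes, out / "genomes.gb")
    write_newick(study.tree, out / "tree.nwk")
    study.matrix.to_tsv(out / "modes.tsv")
    click.echo(f"wrote genomes.gb, tree.nwk, modes.tsv to {out}")
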