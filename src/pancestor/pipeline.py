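"""End-to-end orchestration of the comparative pan-genome analysis.

``run_pipeline`` reads a dataset directory (groups file, genome table,
pseudogene list, Newick tree, optional COG hits), executes every stage —
core sets, phenotype/clade signatures, paralog profile, genome composition
test, ancestral reconstruction, independent contrasts — writes per-stage
TSVs and a single machine-readable ``report.json``. Given identical inputs
and seeds the report is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import yaml

from . import __version__
from . import ancestral, composition, contrasts, coresets, paralogs
from . import datamodel as dm
from .trees import Phylogeny

log = logging.getLogger("pancestor")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


REQUIRED_KEYS = ("groups", "genomes", "tree")


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping of keys to values")
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ConfigError(f"config missing required keys: {missing}")
    base = os.path.dirname(os.path.abspath(path))
    for key in ("groups", "genomes", "tree", "pseudogenes", "coghits"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = os.path.join(base, cfg[key]) \
                if not os.path.isabs(cfg[key]) else cfg[key]
            if not os.path.exists(cfg[key]):
                raise ConfigError(f"config {key}: no such file {cfg[key]!r}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("mc_replicates", 2000)
    cfg.setdefault("presence_mode", "any_copy")
    return cfg


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config_path, out_dir=None) -> dict:
    """Run every stage on one dataset; returns the report dict."""
    cfg = load_config(config_path)
    out_dir = out_dir or os.path.join(
        os.path.dirname(os.path.abspath(config_path)), "pancestor_out"
    )
    os.makedirs(out_dir, exist_ok=True)
    report = {
        "versions": {"pancestor": __version__},
        "seed": cfg["seed"],
        "inputs": {
            k: _file_hash(cfg[k])
            for k in ("groups", "genomes", "tree", "pseudogenes", "coghits")
            if cfg.get(k)
        },
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            result = fn()
        except Exception:
            log.error("stage %s: FAILED", name)
            raise
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
        return result

    # data_model ----------------------------------------------------------
    def _load():
        groups = dm.parse_groups(cfg["groups"])
        genomes = dm.parse_genomes(cfg["genomes"])
        pseudogenes = dm.parse_pseudogenes(cfg["pseudogenes"]) \
            if cfg.get("pseudogenes") else set()
        matrix = dm.build_matrix(groups, genomes, pseudogenes)
        tree = Phylogeny.from_path(cfg["tree"])
        hits = dm.parse_coghits(cfg["coghits"]) if cfg.get("coghits") else None
        return groups, genomes, matrix, tree, hits

    groups, genomes, matrix, tree, hits = stage("data_model", _load)

    # core_sets -----------------------------------------------------------
    def _cores():
        out = {}
        strict = coresets.compute_core(matrix, coresets.CoreSpec.strict())
        out["strict"] = len(strict)
        for k in range(4):
            rc = coresets.compute_core(matrix, coresets.CoreSpec.relaxed(k))
            out[f"rcf{k}" if k else "rcf"] = len(rc)
        rows = [
            {"group_id": gid,
             "n_missing_finished": len(strict.missing_finished.get(gid, [])),
             "missing": ",".join(strict.missing_finished.get(gid, [])),
             "functional_loss": ",".join(strict.functional_loss.get(gid, []))}
            for gid in sorted(strict.group_ids)
        ]
        _write_tsv(os.path.join(out_dir, "core.tsv"), rows)
        return out

    report["core_sizes"] = stage("core_sets", _cores)

    def _signatures():
        out = {}
        for flag in dm.PHENOTYPE_FLAGS:
            sig = coresets.phenotype_signature(matrix, flag)
            out[flag] = len(sig)
        try:
            out["clade1_exclusive"] = len(
                coresets.clade_signature(matrix, "clade1", "clade2"))
            out["clade2_exclusive"] = len(
                coresets.clade_signature(matrix, "clade2", "clade1"))
        except dm.ValidationError:
            pass  # dataset without clade labels
        return out

    report["signature_sizes"] = stage("signatures", _signatures)

    # paralog_profile -----------------------------------------------------
    def _paralogs():
        summary = paralogs.paralog_stats(matrix)
        summary.table.to_csv(os.path.join(out_dir, "paralogs.tsv"), sep="\t")
        out = {
            "total_paralogous_groups": int(
                (matrix.counts("any_copy") >= 2).any(axis=1).sum()),
        }
        if hits is not None:
            cog_map = paralogs.assign_cogs(groups, hits)
            dist = paralogs.functional_distribution(matrix, cog_map)
            dist.table.to_csv(os.path.join(out_dir, "cogdist.tsv"), sep="\t")
            out["n_groups_with_category"] = sum(
                1 for c in cog_map.values() if c is not None)
        return out

    report["paralogs"] = stage("paralog_profile", _paralogs)

    # genome_composition --------------------------------------------------
    def _composition():
        table = composition.composition_table(genomes)
        test = composition.noncoding_chisq(
            table, B=cfg["mc_replicates"], seed=cfg["seed"])
        rows = [
            {"genome_id": g, "residual": f"{test.residuals[g]:.6g}",
             "bias": test.bias[g]}
            for g in table.columns
        ]
        _write_tsv(os.path.join(out_dir, "composition.tsv"), rows)
        return {
            "chi2_stat": test.chi2_stat,
            "mc_p": test.mc_p,
            "mc_replicates": test.mc_replicates,
            "n_noncoding_biased": int((test.bias == "noncoding").sum()),
            "n_coding_biased": int((test.bias == "coding").sum()),
        }

    report["composition"] = stage("genome_composition", _composition)

    # ancestral_reconstruction -------------------------------------------
    def _ancestral():
        interval = ancestral.root_content_interval(
            matrix, tree, cfg["presence_mode"])
        copy_int = ancestral.copy_number_interval(
            matrix, tree, cfg["presence_mode"])
        sizes = {r.id: float(r.genome_size_bp) for r in genomes}
        size_rec = ancestral.squared_change(tree, sizes, weighted=False)
        gene_counts = {r.id: float(r.gene_count) for r in genomes}
        count_rec = ancestral.squared_change(tree, gene_counts, weighted=False)
        idx = tree.index()
        root_label = idx.labels[idx.root]
        rows = [
            {"node_id": label, "genome_size_bp": f"{size_rec.node_states[label]:.1f}",
             "gene_count": f"{count_rec.node_states[label]:.1f}"}
            for label in [idx.labels[v] for v in range(idx.n_nodes)]
        ]
        _write_tsv(os.path.join(out_dir, "ancestral.tsv"), rows)
        return {
            "root_interval_presence": [interval.min_genes, interval.max_genes],
            "root_interval_copy_number": [copy_int.min_genes, copy_int.max_genes],
            "root_genome_size_bp": size_rec.node_states[root_label],
            "root_gene_count": count_rec.node_states[root_label],
        }

    report["ancestral"] = stage("ancestral_reconstruction", _ancestral)

    # independent_contrasts ----------------------------------------------
    def _contrasts():
        clade_map = {r.id: r.clade for r in genomes}
        sizes = {r.id: float(r.genome_size_bp) for r in genomes}
        summary = paralogs.paralog_stats(matrix)
        copies = {
            g: float(summary.table.at[g, "paralogous_copies"])
            for g in matrix.genome_ids
        }
        ct_size = contrasts.pic(tree, sizes, clade_map=clade_map)
        ct_para = contrasts.pic(tree, copies, clade_map=clade_map)
        ct_size.table.to_csv(
            os.path.join(out_dir, "contrasts_size.tsv"), sep="\t", index=False)
        ct_para.table.to_csv(
            os.path.join(out_dir, "contrasts_paralogs.tsv"), sep="\t",
            index=False)
        out = {}
        rate_size = contrasts.clade_rate_test(ct_size)
        rate_para = contrasts.clade_rate_test(ct_para)
        out["rate_test_genome_size"] = {
            "statistic": rate_size.statistic, "p": rate_size.p_value,
            "method": rate_size.method,
        }
        out["rate_test_paralogs"] = {
            "statistic": rate_para.statistic, "p": rate_para.p_value,
            "method": rate_para.method,
        }
        # regression within clade1 only (the heterogeneous clade)
        t1 = ct_size.table["clade"] == "clade1"
        reg = contrasts.origin_regression(
            ct_size.table.loc[t1, "contrast"].to_numpy(),
            ct_para.table.loc[t1, "contrast"].to_numpy(),
        )
        out["origin_regression_clade1"] = {
            "slope": reg.slope, "r": reg.r, "p": reg.p_value, "n": reg.n,
        }
        return out

    report["contrasts"] = stage("independent_contrasts", _contrasts)

    path = os.path.join(out_dir, "report.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", path)
    return report


def _write_tsv(path, rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if not rows:
            fh.write("\n")
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
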