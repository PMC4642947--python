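"""End-to-end orchestration from a YAML config.

A run reads the alignment (and optional structures / mutation lists /
domain boundaries), fits the coevolution network, and writes matrices,
profiles, node lists, a metrics report with one row per configured
network, annotated edge maps, surface patches and a provenance manifest.
Runs are deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, coevo, msa, mutnet, netmetrics, structmap, synthdata
from .errors import ConfigError, CoevnetError
from .model import CoevolutionNetwork
from .netmetrics import NetworkMetrics

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "network", "sum_pos", "n_corr", "n_pos", "n_matrix",
    "density", "strength_raw", "C", "S_M",
]


@dataclass
class RunConfig:
    """Validated run configuration (mirrors the CLI flags)."""

    msa_path: str
    msa_format: str = "fasta"
    structures: list = field(default_factory=list)   # [{path, chain?}]
    mutation_lists: Optional[str] = None             # TSV path
    domains: dict = field(default_factory=dict)      # name -> [start, end]
    weighting: str = "identity_cluster"
    theta: float = 0.62
    pseudocount: float = 1.0
    rho: float = 1e-3
    n_null: int = 100
    seed: int = 0
    window: int = 6
    node_sigma: float = 2.0
    edge_sigma: float = 3.0
    contact_cutoff: float = 12.0
    long_range_cutoff: float = 20.0
    n_dummies: int = 1000
    output_dir: str = "coevnet_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name, value in (
            ("n_null", self.n_null), ("window", self.window),
            ("node_sigma", self.node_sigma), ("edge_sigma", self.edge_sigma),
            ("contact_cutoff", self.contact_cutoff),
            ("long_range_cutoff", self.long_range_cutoff),
        ):
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not Path(self.msa_path).exists():
            raise ConfigError(f"MSA file not found: {self.msa_path}")
        for s in self.structures:
            p = s["path"] if isinstance(s, dict) else s
            if not Path(p).exists():
                raise ConfigError(f"structure file not found: {p}")
        if self.mutation_lists and not Path(self.mutation_lists).exists():
            raise ConfigError(
                f"mutation list file not found: {self.mutation_lists}"
            )
        for name, rng in self.domains.items():
            if len(rng) != 2 or rng[0] > rng[1] or rng[0] < 1:
                raise ConfigError(f"domain {name!r}: bad range {rng}")

    def settings(self) -> coevo.EstimatorSettings:
        return coevo.EstimatorSettings(
            weighting=self.weighting, theta=self.theta,
            pseudocount=self.pseudocount, rho=self.rho,
        )

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def report_table(rows: list[NetworkMetrics]) -> pd.DataFrame:
    """Metrics rows in the printed column order, with a verification pass
    recomputing C and S_M from the raw aggregate columns (2-dp
    round-trip)."""
    frame = pd.DataFrame([m.as_row() for m in rows], columns=REPORT_COLUMNS)
    if frame.empty:
        return frame
    rand = frame[frame["network"].str.startswith("randomized")]
    if not rand.empty:
        ref = rand.iloc[0]
        ref_m = NetworkMetrics(
            label=ref["network"], sum_pos=ref["sum_pos"],
            n_corr=ref["n_corr"], n_pos=ref["n_pos"],
            n_matrix=int(ref["n_matrix"]),
        )
        for _, row in frame.iterrows():
            if row["C"] is None or np.isnan(row["C"]):
                continue
            check = NetworkMetrics.from_aggregates(
                row["sum_pos"], row["n_corr"], row["n_pos"],
                int(row["n_matrix"]), null_ref=ref_m,
            )
            for col, got in (("C", check.C), ("S_M", check.S_M)):
                if abs(round(got, 2) - round(row[col], 2)) > 1e-9:
                    raise CoevnetError(
                        f"report verification failed for "
                        f"{row['network']}/{col}: {got:.4f} vs {row[col]:.4f}"
                    )
    return frame


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure aborts the run with a stage-named error; outputs
    written so far are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.__dict__.copy(),
        "config_sha256": config.digest(),
        "version": __version__,
        "stages": {},
    }
    stage = "read-msa"
    try:
        t0 = _stage(stage)
        aln = msa.read_alignment(config.msa_path, format=config.msa_format)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "fit"
        t0 = _stage(stage)
        net = CoevolutionNetwork(
            aln, settings=config.settings(), window=config.window,
            domains={k: tuple(v) for k, v in config.domains.items()},
        )
        res = net.fit(n_null=config.n_null, seed=config.seed,
                      node_sigma=config.node_sigma)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "write-core"
        t0 = _stage(stage)
        res.matrix.write_tsv(out / "matrix.tsv")
        res.matrix.write_edge_list(out / "edges.tsv")
        res.per_position_frame().to_csv(out / "per_position.tsv",
                                        sep="\t", index=False)
        res.nodes_frame().to_csv(out / "nodes.tsv", sep="\t", index=False)
        res.null.to_json(out / "null_library.json")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "metrics"
        t0 = _stage(stage)
        rows = [res.randomized_row]
        names = ["complete"] + list(config.domains)
        dom = list(config.domains)
        names += [f"{a}-{b}" for i, a in enumerate(dom) for b in dom[i + 1:]]
        for name in names:
            rows.append(res.metrics(name))
        if len(res.primary_nodes) >= 3:
            rows.append(res.three_node_metrics())
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "mutation-networks"
        if config.mutation_lists:
            t0 = _stage(stage)
            lists = mutnet.read_mutation_lists(config.mutation_lists)
            sig: dict = {}
            for label, mlist in lists.items():
                mask = mutnet.build_mask(mlist, None, res.matrix.L)
                metrics, _cent = mutnet.masked_network(
                    res.matrix, mask, res.randomized_row)
                metrics.label = f"{label}(mask)"
                rows.append(metrics)
                pop = mutnet.dummy_population(
                    res.matrix, mlist, n_dummies=config.n_dummies,
                    seed=config.seed, null_ref=res.randomized_row,
                )
                sig[label] = {
                    "real_S_M": metrics.S_M, "real_C": metrics.C,
                    "dummy_S_M_ratio": [pop.sm_ratio_mean, pop.sm_ratio_sigma],
                    "dummy_C_ratio": [pop.c_ratio_mean, pop.c_ratio_sigma],
                    "n_dummies": pop.n_dummies, "seed": pop.seed,
                }
            (out / "mutation_significance.json").write_text(
                json.dumps(sig, indent=1))
            manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "structures"
        for entry in config.structures:
            t0 = _stage(stage)
            path = entry["path"] if isinstance(entry, dict) else entry
            chain = entry.get("chain") if isinstance(entry, dict) else None
            model = structmap.read_structure(path, chain=chain)
            rmap = structmap.map_structure(aln, model)
            cols0 = rmap.columns - 1
            dist = structmap.distance_matrix(model, rmap)
            sub, _sel = netmetrics.submatrix(res.matrix, cols0, cols0)
            sub_mask = res.edge_mask[np.ix_(cols0, cols0)]
            stats = structmap.contact_stats(
                sub, dist, sub_mask,
                contact_cutoff=config.contact_cutoff,
                long_range_cutoff=config.long_range_cutoff,
            )
            edges = structmap.edge_map(sub, sub_mask, rmap, dist)
            stem = Path(path).stem
            edges.to_csv(out / f"edge_map_{stem}.tsv", sep="\t", index=False)
            (out / f"contact_stats_{stem}.json").write_text(
                json.dumps(stats.classes, indent=1))
            # conserved surface patches (entropy-proxy conservation)
            cons = structmap.conservation_from_entropy(res.entropy[cols0])
            acc = structmap.solvent_accessibility(model)[rmap.residue_indices]
            patches = structmap.surface_patches(cons, acc)
            with open(out / f"patches_{stem}.tsv", "w") as fh:
                fh.write("start\tend\tlength\tmean_conservation"
                         "\tmean_accessibility\n")
                for p in patches:
                    fh.write(f"{p.start}\t{p.end}\t{p.length}"
                             f"\t{p.mean_conservation:.4f}"
                             f"\t{p.mean_accessibility:.4f}\n")
            manifest["stages"][f"structure:{stem}"] = round(
                time.perf_counter() - t0, 3)

        stage = "report"
        t0 = _stage(stage)
        frame = report_table(rows)
        frame.to_csv(out / "metrics.tsv", sep="\t", index=False)
        frame.to_json(out / "metrics.json", orient="records", indent=1)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
    except CoevnetError:
        raise
    except Exception as exc:  # annotate the failing stage
        raise CoevnetError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    return out


def simulate(output_dir: str | Path, seed: int = 1) -> Path:
    """Write the reference synthetic bundle (FASTA + PDB + mutation TSV +
    ground truth JSON) so the pipeline can consume synthetic data exactly
    like real data."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln, truth, spec = synthdata.reference_bundle(seed=seed)
    aln.write_fasta(out / "alignment.fasta")
    targeted, background = synthdata.generate_mutation_lists(
        truth, overlap=1.0, size=12, L=spec.L, seed=seed)
    synthdata.write_mutation_list_tsv([targeted, background],
                                      out / "mutations.tsv")
    # the toy structure carries the first row's sequence so that
    # structure mapping threads it back into the alignment
    seq = aln.ungapped(0).replace("X", "A")
    model, _ = synthdata.generate_structure(len(seq), sequence=seq, seed=seed)
    synthdata.write_pdb(model, out / "structure.pdb")
    truth.to_json(out / "ground_truth.json")
    cfg = RunConfig(
        msa_path=str(out / "alignment.fasta"),
        mutation_lists=str(out / "mutations.tsv"),
        structures=[str(out / "structure.pdb")],
        n_null=10, seed=seed, n_dummies=200,
        output_dir=str(out / "run"),
    )
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.__dict__))
    return out
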