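"""End-to-end orchestration: synthesize → predict → interpret → overlap →
stability → mediation → transfer, with a checksummed artifact manifest.

Every stochastic stage takes its seed from the resolved :class:`RunConfig`,
so two runs from the same config produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .connectome import Atlas
from .exceptions import InvalidParameterError
from .interpretation import average_maps, network_summary, node_summary, overlap
from .mediation import mediate_topk
from .prediction import ConnectomePLS
from .stability import bootstrap_weights, network_restricted_cv, weight_intercorrelation
from .synthetic import default_spec, simulate_cohort
from .transfer import apply_model, save_model, validate_transfer

__all__ = ["RunConfig", "full_run", "scaled_canonical_atlas"]

_CANONICAL_SIZES = {
    "VIS": 30, "SMN": 36, "DAN": 28, "VAN": 26,
    "LIM": 24, "FPN": 30, "DMN": 36, "SUB": 36,
}


def scaled_canonical_atlas(n_nodes: int = 60) -> Atlas:
    """An 8-network atlas with canonical labels scaled to ``n_nodes``.

    Network sizes are proportional to the 246-node default (largest-remainder
    rounding), keeping the within/between edge-class structure while allowing
    desk-scale problem sizes.
    """
    if n_nodes < 16:
        raise InvalidParameterError("need at least 2 nodes per network (16 total)")
    total = sum(_CANONICAL_SIZES.values())
    raw = {k: n_nodes * v / total for k, v in _CANONICAL_SIZES.items()}
    sizes = {k: max(int(v), 2) for k, v in raw.items()}
    while sum(sizes.values()) < n_nodes:
        k = max(raw, key=lambda k: raw[k] - sizes[k])
        sizes[k] += 1
    while sum(sizes.values()) > n_nodes:
        k = min(raw, key=lambda k: raw[k] - sizes[k])
        sizes[k] -= 1
    node_ids, node_labels, nets = [], [], []
    i = 0
    for net, s in sizes.items():
        for j in range(s):
            i += 1
            node_ids.append(f"n{i:03d}")
            node_labels.append(f"{net}_{j + 1:02d}")
            nets.append(net)
    return Atlas(tuple(node_ids), tuple(node_labels), tuple(nets))


@dataclass
class RunConfig:
    """Resolved settings for every pipeline stage."""

    out_dir: str
    seed: int = 0
    # synthetic stage (ignored when input paths are given)
    n_nodes: int = 60
    n_subjects: int = 200
    noise_sd: float = 0.5
    # optional user data
    phenotypes_path: str | None = None
    edges_path: str | None = None
    atlas_path: str | None = None
    # prediction
    targets: tuple = ("age", "gF")
    folds: int = 10
    reps: int = 20
    n_components: int | None = 5
    n_perm: int = 0  # permutation test iterations per target (0 = skip)
    # interpretation / overlap
    overlap_n_perm: int = 1000
    # stability
    stability_target: str = "age"
    n_boot: int = 200
    restricted_reps: int = 2
    # mediation
    mediation_outcome: str = "gF"
    mediation_k: int = 50
    mediation_n_boot: int = 500
    # transfer
    transfer_n_subjects: int = 200

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "targets" in d:
            d["targets"] = tuple(d["targets"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = list(d["targets"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def full_run(config: RunConfig) -> dict:
    """Run every stage and return the artifact manifest (also written).

    On synthetic data the discovery cohort comes from the generator's default
    conditions at the configured size; with ``phenotypes_path``/``edges_path``
    set, user data are loaded instead and the synth stage is skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    rng = np.random.default_rng(config.seed)

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        return path

    save("config.json", lambda p: io.write_json(config.to_dict(), p))

    # ---- stage: synth / load -------------------------------------------
    if config.edges_path and config.phenotypes_path:
        phen = io.read_phenotypes(config.phenotypes_path)
        edges, _ = io.read_edges(config.edges_path)
        atlas = (
            io.read_atlas(config.atlas_path) if config.atlas_path
            else scaled_canonical_atlas(config.n_nodes)
        )
    else:
        atlas = scaled_canonical_atlas(config.n_nodes)
        spec = default_spec(
            atlas, config.n_subjects, noise_sd=config.noise_sd, seed=config.seed
        )
        phen, edges = simulate_cohort(spec)
        save("phenotypes.tsv", lambda p: io.write_phenotypes(phen, p))
        save("edges.tsv", lambda p: io.write_edges(edges, phen["subject_id"], p))
        save("atlas.tsv", lambda p: io.write_atlas(atlas, p))

    # ---- stage: predict + interpret ------------------------------------
    conn_maps = {}
    cv_store = {}
    for target in config.targets:
        model = ConnectomePLS.from_dataframe(phen, edges, target, atlas=atlas)
        cv = model.fit_repeated_cv(
            folds=config.folds,
            reps=config.reps,
            n_components=config.n_components,
            seed=int(rng.integers(2**31)),
        )
        cv_store[target] = cv
        summary = cv.summary()
        metrics = {
            row["metric"]: {"mean": row["mean"], "sd": row["sd"]}
            for _, row in summary.iterrows()
        }
        metrics["n_fold_weight_maps"] = int(cv.fold_weight_maps.shape[0])
        save(f"metrics_{target}.json", lambda p, m=metrics: io.write_json(m, p))
        save(
            f"predictions_{target}.tsv",
            lambda p, c=cv: io.write_weight_table(c.predicted, p, id_col="subject"),
        )
        if config.n_perm > 0:
            perm = model.permutation_test(
                n_perm=config.n_perm,
                folds=config.folds,
                n_components=config.n_components,
                seed=int(rng.integers(2**31)),
                observed=cv.mean_r,
            )
            save(
                f"permutation_{target}.json",
                lambda p, pr=perm: io.write_json(
                    {
                        "observed": pr.observed,
                        "p_value": pr.p_value,
                        "n_perm": pr.n_perm,
                        "null_values": list(pr.null_values),
                    },
                    p,
                ),
            )
        wmap = average_maps(
            cv.fold_weight_maps, source={"target": target, "stage": "cv"}
        )
        conn_maps[target] = wmap
        nmap = node_summary(wmap, atlas)
        cells, _ = network_summary(wmap, atlas)
        save(f"weights_{target}.tsv", lambda p, w=wmap: io.write_weight_table(w.values, p))
        save(
            f"nodes_{target}.tsv",
            lambda p, w=nmap: io.write_weight_table(w.values, p, id_col="node_id"),
        )
        save(f"cells_{target}.tsv", lambda p, c=cells: io.write_network_cells(c.cells, p))

    # ---- stage: overlap -------------------------------------------------
    base = config.targets[0]
    overlaps = {}
    for target in config.targets[1:]:
        per_level = {}
        for level, fn in (
            ("connection", None),
            ("node", lambda w: node_summary(w, atlas)),
            ("network", lambda w: network_summary(w, atlas)[1]),
        ):
            a = conn_maps[base] if fn is None else fn(conn_maps[base])
            b = conn_maps[target] if fn is None else fn(conn_maps[target])
            res = overlap(
                a, b, n_perm=config.overlap_n_perm, seed=int(rng.integers(2**31))
            )
            per_level[level] = {"r": res.r, "p": res.p, "n_perm": res.n_perm}
        overlaps[f"{base}_vs_{target}"] = per_level
    save("overlap.json", lambda p: io.write_json(overlaps, p))

    # ---- stage: stability ----------------------------------------------
    st_target = config.stability_target
    model = ConnectomePLS.from_dataframe(phen, edges, st_target, atlas=atlas)
    ic_mean, ic_sd = weight_intercorrelation(
        cv_store[st_target].fold_weight_maps, seed=int(rng.integers(2**31))
    )
    boot_map, _, _ = bootstrap_weights(
        model.exog,
        model.endog,
        n_boot=config.n_boot,
        n_components=config.n_components or 5,
        seed=int(rng.integers(2**31)),
    )
    table, whole_r, size_corr = network_restricted_cv(
        model.exog,
        model.endog,
        atlas,
        folds=config.folds,
        reps=config.restricted_reps,
        n_components=config.n_components or 5,
        seed=int(rng.integers(2**31)),
        target_name=st_target,
    )
    save("network_restricted.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
    save(
        "stability.json",
        lambda p: io.write_json(
            {
                "target": st_target,
                "intercorrelation_mean": ic_mean,
                "intercorrelation_sd": ic_sd,
                "whole_brain_r": whole_r,
                "max_restricted_r": float(table["mean_r"].max()),
                "size_vs_accuracy_corr": size_corr,
            },
            p,
        ),
    )
    save(
        "bootstrap_weights.tsv",
        lambda p: io.write_weight_table(boot_map.values, p),
    )

    # ---- stage: mediation ----------------------------------------------
    med_out = config.mediation_outcome
    if med_out in conn_maps and med_out in phen.columns:
        complete = phen[med_out].notna().to_numpy()
        med = mediate_topk(
            conn_maps[med_out],
            edges[complete],
            phen.loc[complete, "age"].to_numpy(),
            phen.loc[complete, med_out].to_numpy(),
            np.column_stack(
                [phen.loc[complete, "gender"], phen.loc[complete, "mean_fd"]]
            ),
            k=config.mediation_k,
            sign="positive",
            n_boot=config.mediation_n_boot,
            seed=int(rng.integers(2**31)),
        )
        save(
            "mediation.tsv",
            lambda p: med.records.to_csv(p, sep="\t", index=False),
        )
        lo, hi = med.proportion_range()
        save(
            "mediation_summary.json",
            lambda p: io.write_json(
                {
                    "outcome": med_out,
                    "k": med.k,
                    "n_significant": med.n_significant,
                    "proportion_mediated_min": lo,
                    "proportion_mediated_max": hi,
                },
                p,
            ),
        )

    # ---- stage: transfer ------------------------------------------------
    frozen = {}
    for target in config.targets:
        m = ConnectomePLS.from_dataframe(phen, edges, target, atlas=atlas)
        res = m.fit(n_components=config.n_components or 5)
        frozen[target] = res
        save(f"model_{target}.json", lambda p, r=res: save_model(r, p))
    ext_spec = default_spec(
        atlas,
        config.transfer_n_subjects,
        noise_sd=config.noise_sd,
        seed=config.seed,
    ).with_(seed=config.seed + 104729)
    ext_phen, ext_edges = simulate_cohort(ext_spec)
    transfer_out = {}
    for target, res in frozen.items():
        predicted = apply_model(res, ext_edges, atlas_hash=atlas.content_hash())
        tr = validate_transfer(
            predicted,
            ext_phen["age"].to_numpy(),
            ext_phen["mean_fd"].to_numpy(),
            n_models_tested=len(frozen),
            target_name=target,
        )
        transfer_out[target] = {
            "partial_r": tr.partial_r,
            "p": tr.p,
            "bonferroni_alpha": tr.bonferroni_alpha,
            "passed": tr.passed,
        }
    save("transfer.json", lambda p: io.write_json(transfer_out, p))

    manifest = {
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "seed": config.seed,
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
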