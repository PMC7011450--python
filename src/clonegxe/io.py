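"""Plain-text persistence: CSV tables and chain directories.

Every artifact the pipeline writes is plain CSV or JSON so that any
single stage can be driven (or inspected) independently.  Missing values
are encoded as empty fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from clonegxe.mixed_model import MCMCOptions, PosteriorChains, ScalingRecord

__all__ = [
    "read_trial",
    "write_trial",
    "save_chains",
    "load_chains",
    "save_scaling",
    "load_scaling",
    "sha256_file",
]

TRIAL_COLUMNS = ["site", "rep", "block", "population", "genotype", "ramet", "trait", "value"]


def read_trial(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in TRIAL_COLUMNS if c != "value"})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def write_trial(df: pd.DataFrame, path):
    df[TRIAL_COLUMNS].to_csv(path, index=False, na_rep="")


def _flatten_cov(G: np.ndarray, envs: list[str]) -> pd.DataFrame:
    cols = {}
    for i, a in enumerate(envs):
        for j, b in enumerate(envs):
            if j < i:
                continue
            cols[f"{a}:{b}"] = G[:, i, j]
    return pd.DataFrame(cols)


def _unflatten_cov(df: pd.DataFrame, envs: list[str]) -> np.ndarray:
    n, S = len(envs), len(df)
    G = np.empty((S, n, n))
    for i, a in enumerate(envs):
        for j, b in enumerate(envs):
            key = f"{a}:{b}" if j >= i else f"{b}:{a}"
            G[:, i, j] = df[key].to_numpy()
    return G


def save_chains(chains: PosteriorChains, outdir):
    """One CSV per parameter group plus a metadata sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    envs = chains.environments
    pd.DataFrame(chains.beta, columns=envs).to_csv(out / "beta.csv", index_label="sample")
    for name, G in (("G1", chains.G1), ("G2", chains.G2)):
        if G is not None:
            _flatten_cov(G, envs).to_csv(out / f"{name}.csv", index_label="sample")
    for name, arr in (("s2_rep", chains.s2_rep), ("s2_block", chains.s2_block), ("s2_e", chains.s2_e)):
        if arr is not None:
            pd.DataFrame(arr, columns=envs).to_csv(out / f"{name}.csv", index_label="sample")
    for name, mat, idx in (
        ("pop_effect_mean", chains.pop_effect_mean, chains.populations),
        ("gen_effect_mean", chains.gen_effect_mean, chains.genotypes),
    ):
        if mat is not None:
            pd.DataFrame(mat, index=idx, columns=envs).to_csv(out / f"{name}.csv", index_label="level")
    meta = {
        "trait": chains.trait,
        "environments": envs,
        "options": {
            "iterations": chains.options.iterations,
            "burn_in": chains.options.burn_in,
            "thinning": chains.options.thinning,
            "seed": chains.options.seed,
        },
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_chains(outdir) -> PosteriorChains:
    out = Path(outdir)
    meta = json.loads((out / "meta.json").read_text())
    envs = meta["environments"]

    def maybe(name):
        p = out / f"{name}.csv"
        return pd.read_csv(p, index_col=0) if p.exists() else None

    g1, g2 = maybe("G1"), maybe("G2")
    pop_mean, gen_mean = maybe("pop_effect_mean"), maybe("gen_effect_mean")
    s2_rep, s2_block = maybe("s2_rep"), maybe("s2_block")
    return PosteriorChains(
        trait=meta["trait"],
        environments=envs,
        options=MCMCOptions(**meta["options"]),
        beta=pd.read_csv(out / "beta.csv", index_col=0).to_numpy(),
        G1=None if g1 is None else _unflatten_cov(g1, envs),
        G2=None if g2 is None else _unflatten_cov(g2, envs),
        s2_rep=None if s2_rep is None else s2_rep.to_numpy(),
        s2_block=None if s2_block is None else s2_block.to_numpy(),
        s2_e=pd.read_csv(out / "s2_e.csv", index_col=0).to_numpy(),
        populations=None if pop_mean is None else [str(i) for i in pop_mean.index],
        genotypes=None if gen_mean is None else [str(i) for i in gen_mean.index],
        pop_effect_mean=None if pop_mean is None else pop_mean.to_numpy(),
        gen_effect_mean=None if gen_mean is None else gen_mean.to_numpy(),
    )


def save_scaling(scaling: ScalingRecord, path):
    payload = [
        {"site": site, "trait": trait, "mean": m, "sd": s}
        for (site, trait), (m, s) in scaling.params.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_scaling(path) -> ScalingRecord:
    payload = json.loads(Path(path).read_text())
    return ScalingRecord(
        {(r["site"], r["trait"]): (r["mean"], r["sd"]) for r in payload}
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
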