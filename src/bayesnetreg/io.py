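"""File formats and real-data plumbing.

Networks travel either as one square CSV per sample (header row = taxon
labels) or as a single long-format table with columns ``sample_id, taxon_a,
taxon_b, weight`` (rows with ``taxon_a == taxon_b`` carry diagonal /
presence values).  Responses are two-column CSVs ``sample_id,response``.
Trees are Newick.  Draws, summaries and reports are CSV/JSON.  All floats are
written with 17 significant digits so round trips are bit-stable.

Also implements the observational-data path: OTU prevalence filtering and the
construction of per-sample networks by restricting a meta-network (an
externally inferred co-occurrence network over all samples) to the OTUs
present in each sample.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .core import Hyperparameters, IndexMap, NetworkDataset
from .gibbs import ConvergenceReport, PosteriorSamples, RunConfig
from .simulate import PhyloTree

FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Networks and responses
# ---------------------------------------------------------------------------

def write_networks(dataset: NetworkDataset, outdir: str | Path) -> None:
    """One square CSV per sample (header = taxon labels), zero-padded names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = len(str(dataset.n))
    for i in range(dataset.n):
        df = pd.DataFrame(dataset.adjacency[i], columns=dataset.taxa)
        df.to_csv(outdir / f"sample_{i:0{width}d}.csv", index=False, float_format=FLOAT_FMT)


def write_networks_long(dataset: NetworkDataset, path: str | Path) -> None:
    """Single long-format TSV (sample_id, taxon_a, taxon_b, weight); zeros dropped."""
    rows = []
    iu = np.triu_indices(dataset.V)
    for i in range(dataset.n):
        A = dataset.adjacency[i]
        for r, c in zip(*iu):
            if A[r, c] != 0.0:
                rows.append((f"sample_{i}", dataset.taxa[r], dataset.taxa[c], A[r, c]))
    pd.DataFrame(rows, columns=["sample_id", "taxon_a", "taxon_b", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_networks(path: str | Path, taxa: list[str] | None = None) -> NetworkDataset:
    """Read networks from a per-sample CSV directory or a long-format table.

    The response is filled with zeros; attach it with :func:`read_response`
    or by constructing a fresh :class:`NetworkDataset`.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("sample_*.csv"))
        if not files:
            raise FileNotFoundError(f"no sample_*.csv files under {path}")
        mats, labels = [], None
        for f in files:
            df = pd.read_csv(f, float_precision="round_trip")
            if labels is None:
                labels = list(df.columns)
            elif list(df.columns) != labels:
                raise ValueError(f"{f.name}: taxon header differs from {files[0].name}")
            mats.append(df.to_numpy(dtype=float))
        return NetworkDataset(adjacency=np.stack(mats), response=np.zeros(len(mats)),
                              taxa=labels)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample_id", "taxon_a", "taxon_b", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: long-format table missing columns {sorted(missing)}")
    if taxa is None:
        taxa = sorted(set(df["taxon_a"]) | set(df["taxon_b"]))
    index = {t: i for i, t in enumerate(taxa)}
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    V = len(taxa)
    mats = {sid: np.zeros((V, V)) for sid in sample_ids}
    for rec in df.itertuples(index=False):
        try:
            a, b = index[rec.taxon_a], index[rec.taxon_b]
        except KeyError as exc:
            raise ValueError(f"{path}: unknown taxon {exc.args[0]!r}") from None
        A = mats[rec.sample_id]
        A[a, b] = A[b, a] = rec.weight
    return NetworkDataset(adjacency=np.stack([mats[s] for s in sample_ids]),
                          response=np.zeros(len(sample_ids)), taxa=list(taxa))


def write_response(response: np.ndarray, path: str | Path, sample_ids=None) -> None:
    ids = sample_ids or [f"sample_{i}" for i in range(len(response))]
    pd.DataFrame({"sample_id": ids, "response": response}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_response(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    if "response" not in df.columns:
        raise ValueError(f"{path}: expected a 'response' column")
    return df["response"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def write_tree(ptree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(ptree.as_newick() + "\n")


def read_tree(path_or_newick: str | Path) -> PhyloTree:
    """Parse a Newick tree; leaf labels are ordered lexicographically."""
    text = str(path_or_newick)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick")
    labels = sorted(t.label for t in tree.taxon_namespace)
    return PhyloTree(tree=tree, labels=labels)


# ---------------------------------------------------------------------------
# Posterior draws
# ---------------------------------------------------------------------------

def write_draws(samples: PosteriorSamples, outdir: str | Path) -> None:
    """CSV per chain per parameter block, plus JSON metadata and report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    imap = samples.index_map
    gcols = [f"g_{imap.rows[j]}_{imap.cols[j]}" for j in range(imap.q)]
    xcols = [f"xi_{k}" for k in range(imap.V)]
    for c in range(samples.gamma.shape[0]):
        pd.DataFrame(samples.gamma[c], columns=gcols).to_csv(
            outdir / f"gamma_chain{c}.csv", index=False, float_format=FLOAT_FMT)
        pd.DataFrame(samples.xi[c], columns=xcols).to_csv(
            outdir / f"xi_chain{c}.csv", index=False)
        pd.DataFrame({"mu": samples.mu[c], "tau2": samples.tau2[c]}).to_csv(
            outdir / f"scalars_chain{c}.csv", index=False, float_format=FLOAT_FMT)
    meta = {
        "V": imap.V,
        "include_diagonal": imap.include_diagonal,
        "n_chains": samples.gamma.shape[0],
        "hyper": vars(samples.hyper),
        "config": vars(samples.config),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    (outdir / "convergence.json").write_text(json.dumps(samples.report.to_dict(), indent=2))


def read_draws(indir: str | Path) -> PosteriorSamples:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    imap = IndexMap(meta["V"], include_diagonal=meta["include_diagonal"])
    gamma, xi, mu, tau2 = [], [], [], []
    for c in range(meta["n_chains"]):
        gamma.append(pd.read_csv(indir / f"gamma_chain{c}.csv", float_precision="round_trip").to_numpy(dtype=float))
        xi.append(pd.read_csv(indir / f"xi_chain{c}.csv").to_numpy(dtype=np.int8))
        sc = pd.read_csv(indir / f"scalars_chain{c}.csv", float_precision="round_trip")
        mu.append(sc["mu"].to_numpy())
        tau2.append(sc["tau2"].to_numpy())
    rep = json.loads((indir / "convergence.json").read_text())
    return PosteriorSamples(
        gamma=np.stack(gamma), xi=np.stack(xi), mu=np.stack(mu), tau2=np.stack(tau2),
        index_map=imap, hyper=Hyperparameters(**meta["hyper"]),
        config=RunConfig(**meta["config"]),
        report=ConvergenceReport(**rep),
    )


# ---------------------------------------------------------------------------
# Meta-network path for observational data
# ---------------------------------------------------------------------------

@dataclass
class MetaNetwork:
    """Undirected weighted edge list over OTU labels (no self loops)."""

    labels: list[str]
    edges: pd.DataFrame  # columns taxon_a, taxon_b, weight

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("meta-network labels must be unique")
        known = set(self.labels)
        for rec in self.edges.itertuples(index=False):
            if rec.taxon_a == rec.taxon_b:
                raise ValueError(f"self loop on {rec.taxon_a!r} in meta-network edge list")
            if rec.taxon_a not in known or rec.taxon_b not in known:
                raise ValueError(f"edge ({rec.taxon_a!r}, {rec.taxon_b!r}) uses unknown label")

    @classmethod
    def from_file(cls, path: str | Path) -> "MetaNetwork":
        df = pd.read_csv(path, sep=None, engine="python")
        missing = {"taxon_a", "taxon_b"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: edge list missing columns {sorted(missing)}")
        if "weight" not in df.columns:
            df["weight"] = 1.0
        labels = sorted(set(df["taxon_a"]) | set(df["taxon_b"]))
        return cls(labels=labels, edges=df[["taxon_a", "taxon_b", "weight"]])

    def adjacency(self, edge_values: str = "weights") -> np.ndarray:
        index = {t: i for i, t in enumerate(self.labels)}
        V = len(self.labels)
        A = np.zeros((V, V))
        for rec in self.edges.itertuples(index=False):
            w = rec.weight if edge_values == "weights" else 1.0
            a, b = index[rec.taxon_a], index[rec.taxon_b]
            A[a, b] = A[b, a] = w
        return A


def filter_otus(table: pd.DataFrame, min_samples: int = 40) -> pd.DataFrame:
    """Keep OTUs (columns) with nonzero abundance in at least ``min_samples`` rows."""
    counts = (table != 0).sum(axis=0)
    kept = table.loc[:, counts >= min_samples]
    if kept.shape[1] == 0:
        warnings.warn(f"no OTU occurs in at least {min_samples} samples", UserWarning)
    return kept


def build_sample_networks(meta: MetaNetwork, presence, edge_values: str = "weights",
                          response: np.ndarray | None = None) -> NetworkDataset:
    """Restrict the meta-network to each sample's observed OTUs.

    ``presence`` is a list of label collections, one per sample.  An edge is
    kept only when both endpoints are present; the diagonal is 1 for present
    OTUs and 0 otherwise.
    """
    base = meta.adjacency(edge_values=edge_values)
    index = {t: i for i, t in enumerate(meta.labels)}
    V = len(meta.labels)
    mats = []
    for i, labels in enumerate(presence):
        mask = np.zeros(V, dtype=bool)
        for lab in labels:
            if lab not in index:
                raise ValueError(f"sample {i}: OTU {lab!r} not in the meta-network")
            mask[index[lab]] = True
        A = np.where(np.outer(mask, mask), base, 0.0)
        np.fill_diagonal(A, mask.astype(float))
        mats.append(A)
    resp = response if response is not None else np.zeros(len(mats))
    return NetworkDataset(adjacency=np.stack(mats), response=resp, taxa=list(meta.labels))


def presence_from_adjacency(dataset: NetworkDataset) -> list[np.ndarray]:
    """Per-sample indices of taxa with any nonzero row or diagonal entry."""
    out = []
    for i in range(dataset.n):
        A = dataset.adjacency[i]
        out.append(np.flatnonzero((np.abs(A).sum(axis=1) > 0) | (np.diag(A) != 0)))
    return out


# ---------------------------------------------------------------------------
# Config and manifests
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    "R": int,
    "nu": (int, float, type(None)),
    "eta": (int, float),
    "chains": int,
    "min_samples": int,
    "max_samples": int,
    "seed": int,
}
_REQUIRED_KEYS = ("R", "seed")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run config, validating keys and types."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    for key in _REQUIRED_KEYS:
        if key not in data:
            raise ConfigError(f"{path}: missing required config key {key!r}")
    for key, value in data.items():
        expected = _CONFIG_SCHEMA.get(key)
        if expected is not None and not isinstance(value, expected):
            raise ConfigError(
                f"{path}: config key {key!r} has type {type(value).__name__}, "
                f"expected {expected}"
            )
    return data


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: str | Path, config: dict, seeds, inputs=()) -> Path:
    """Record config, seeds, version and input digests so a run can be replayed."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "seeds": list(np.atleast_1d(seeds).tolist()),
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
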