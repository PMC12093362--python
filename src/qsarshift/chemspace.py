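"""Chemical-space diagnostics between two data domains.

Three complementary views: (i) the mean Tanimoto similarity of each
query compound's nearest neighbour in a reference set — an asymmetric,
fingerprint-level measure of how well one library covers another;
(ii) a seeded 2-D UMAP embedding of a descriptor matrix for visual
inspection; (iii) robust per-property comparison of seven
physicochemical distributions. These are diagnostics of data-set
relatedness only — none of them is asserted to predict transfer
performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_UMAP_PARAMS
from .curation import ClassifiedDataset
from .descriptors import (
    DescriptorMatrix,
    Fingerprint,
    PHYSCHEM_PROPERTIES,
    physchem_table,
)
from .splitting import tanimoto_matrix


@dataclass
class NNSimilarityReport:
    """Per-query nearest-neighbour similarities and their mean."""

    records: list[tuple[str, str, float]]  # (query_key, neighbor_key, similarity)
    mean_nn_similarity: float
    query_domain: str
    reference_domain: str

    def to_rows(self) -> list[dict]:
        return [
            {
                "query_key": q,
                "neighbor_key": r,
                "similarity": s,
                "query_domain": self.query_domain,
                "reference_domain": self.reference_domain,
            }
            for q, r, s in self.records
        ]


def nn_mean_tanimoto(
    query_fps: Sequence[Fingerprint],
    reference_fps: Sequence[Fingerprint],
    query_domain: str = "proprietary_like",
    reference_domain: str = "public_like",
) -> NNSimilarityReport:
    """Mean similarity of each query compound's nearest reference neighbour.

    Asymmetric by construction; the default direction asks how well the
    public-like library covers the proprietary-like one.
    """
    if len(query_fps) == 0 or len(reference_fps) == 0:
        raise ValueError("both fingerprint sets must be non-empty")
    sim = tanimoto_matrix(query_fps, reference_fps)
    nn_idx = sim.argmax(axis=1)
    records = [
        (
            query_fps[i].compound_key,
            reference_fps[int(nn_idx[i])].compound_key,
            float(sim[i, nn_idx[i]]),
        )
        for i in range(len(query_fps))
    ]
    return NNSimilarityReport(
        records=records,
        mean_nn_similarity=float(np.mean([s for _, _, s in records])),
        query_domain=query_domain,
        reference_domain=reference_domain,
    )


@dataclass
class EmbeddingResult:
    coordinates: dict[str, tuple[float, float]]
    params: dict
    seed: int
    domain_of: dict[str, str]
    overlap_flags: dict[str, bool]

    def to_rows(self) -> list[dict]:
        return [
            {
                "compound_key": k,
                "x": x,
                "y": y,
                "domain": self.domain_of.get(k, ""),
                "overlap": self.overlap_flags.get(k, False),
            }
            for k, (x, y) in self.coordinates.items()
        ]


def embed_2d(
    matrix: DescriptorMatrix,
    seed: int,
    params: dict | None = None,
    domain_of: dict[str, str] | None = None,
    overlap_keys: set[str] | None = None,
) -> EmbeddingResult:
    """Seeded 2-D UMAP embedding of a descriptor matrix.

    Compounds shared between domains (``overlap_keys``) are flagged so a
    plot can show them as a third category. Requires at least
    ``n_neighbors + 1`` rows.
    """
    p = dict(DEFAULT_UMAP_PARAMS)
    if params:
        p.update(params)
    if p.get("n_components", 2) != 2:
        raise ValueError("the 2-D embedding requires n_components = 2")
    n = matrix.matrix.shape[0]
    minimum = p["n_neighbors"] + 1
    if n < minimum:
        raise ValueError(
            f"embedding needs at least {minimum} rows (n_neighbors + 1); got {n}"
        )
    import umap  # deferred: numba compilation is slow to import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=p["n_neighbors"],
            min_dist=p["min_dist"],
            n_components=2,
            random_state=seed,
        )
        coords = reducer.fit_transform(matrix.matrix)
    keys = list(matrix.compound_keys)
    overlap_keys = overlap_keys or set()
    return EmbeddingResult(
        coordinates={k: (float(x), float(y)) for k, (x, y) in zip(keys, coords)},
        params=p,
        seed=seed,
        domain_of=dict(domain_of or {}),
        overlap_flags={k: k in overlap_keys for k in keys},
    )


def remove_shared_inchis(
    set_a: ClassifiedDataset, set_b: ClassifiedDataset
) -> tuple[ClassifiedDataset, ClassifiedDataset]:
    """Delta sets: each domain without the compounds shared with the other."""
    shared = set_a.inchis & set_b.inchis
    keep_a = [i for i, (r, _) in enumerate(set_a.members) if r.inchi not in shared]
    keep_b = [i for i, (r, _) in enumerate(set_b.members) if r.inchi not in shared]
    return set_a.subset(keep_a), set_b.subset(keep_b)


@dataclass
class PropertyComparison:
    """Per-property robust location comparison between two data sets."""

    table: pd.DataFrame  # indexed by property, columns described below

    def shift(self, prop: str) -> float:
        return float(self.table.loc[prop, "standardized_shift"])


def compare_properties(
    set_a: ClassifiedDataset, set_b: ClassifiedDataset
) -> PropertyComparison:
    """Compare the seven physicochemical properties between two sets.

    For each property the table reports median and quartiles per set and
    a standardized location shift
    ``(median_b - median_a) / (pooled IQR / 1.349)`` — a robust analogue
    of a z-scored mean difference. Identical sets give shift 0; a pooled
    IQR of 0 with unequal medians gives an infinite shift.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both data sets must be non-empty")
    ta, tb = physchem_table(set_a), physchem_table(set_b)
    rows = []
    for prop in PHYSCHEM_PROPERTIES:
        a, b = ta[prop].to_numpy(float), tb[prop].to_numpy(float)
        qa = np.percentile(a, [25, 50, 75])
        qb = np.percentile(b, [25, 50, 75])
        pooled_iqr = ((qa[2] - qa[0]) + (qb[2] - qb[0])) / 2.0
        scale = pooled_iqr / 1.349  # IQR of a normal = 1.349 sigma
        diff = qb[1] - qa[1]
        if scale > 0:
            shift = diff / scale
        else:
            shift = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
        rows.append(
            {
                "property": prop,
                "median_a": qa[1],
                "q1_a": qa[0],
                "q3_a": qa[2],
                "median_b": qb[1],
                "q1_b": qb[0],
                "q3_b": qb[2],
                "standardized_shift": shift,
            }
        )
    return PropertyComparison(pd.DataFrame(rows).set_index("property"))


def plot_embedding(result: EmbeddingResult, path: str) -> None:
    """Scatter plot of a 2-D embedding, coloured by domain, overlap marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    rows = result.to_rows()
    domains = sorted({r["domain"] for r in rows})
    for dom in domains:
        xs = [r["x"] for r in rows if r["domain"] == dom and not r["overlap"]]
        ys = [r["y"] for r in rows if r["domain"] == dom and not r["overlap"]]
        ax.scatter(xs, ys, s=8, alpha=0.6, label=dom or "unlabelled")
    xs = [r["x"] for r in rows if r["overlap"]]
    ys = [r["y"] for r in rows if r["overlap"]]
    if xs:
        ax.scatter(xs, ys, s=12, c="black", marker="x", label="shared")
    ax.legend(fontsize=8)
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
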