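"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each statistic by direct enumeration
(loops, no vectorization, no reuse of package internals) so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from crosscell import ExpressionDataset, SampleAnnotation, SyntheticSpec, generate


# ---------------------------------------------------------------------------
# dataset builders


def make_dataset(
    values: dict[str, list[float]],
    cell_types: dict[str, str],
    species_id: str = "sp",
    level: str = "gene",
) -> ExpressionDataset:
    """Tiny dataset from {feature: row} and {sample: cell_type} mappings."""
    sample_ids = list(cell_types)
    frame = pd.DataFrame.from_dict(values, orient="index", columns=sample_ids).astype(float)
    reps: dict[str, int] = {}
    samples = []
    for sid in sample_ids:
        ct = cell_types[sid]
        reps[ct] = reps.get(ct, 0) + 1
        samples.append(SampleAnnotation(sample_id=sid, cell_type=ct, replicate=reps[ct]))
    return ExpressionDataset(species_id=species_id, values=frame, samples=samples, level=level)


def random_dataset(rng: np.random.Generator, n_genes: int = 40, cell_types=("A", "B", "C"), reps: int = 3):
    samples = {f"{ct}_{r}": ct for ct in cell_types for r in range(1, reps + 1)}
    vals = {
        f"g{i:03d}": list(np.exp2(rng.normal(8, 1.5) + rng.normal(0, 1, size=len(samples))))
        for i in range(n_genes)
    }
    return make_dataset(vals, samples)


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-condition compendium shared by read-only tests."""
    return generate(SyntheticSpec(seed=11))


# ---------------------------------------------------------------------------
# oracles


def brute_es(scores, hit_symbols, symbols, p=1.0):
    """Enumerated weighted running sum; returns the signed extreme deviation."""
    n = len(scores)
    hits = [s in hit_symbols for s in symbols]
    n_hits = sum(hits)
    total = sum(abs(scores[i]) ** p for i in range(n) if hits[i])
    running, best = [], 0.0
    cur_hit_w, cur_miss = 0.0, 0
    for i in range(n):
        if hits[i]:
            cur_hit_w += abs(scores[i]) ** p if total > 0 else 1.0
        else:
            cur_miss += 1
        p_hit = cur_hit_w / (total if total > 0 else n_hits)
        dev = p_hit - cur_miss / (n - n_hits)
        running.append(dev)
        if abs(dev) > abs(best):
            best = dev
    return best, running


def brute_min_vs_max(dataset: ExpressionDataset, index_types, comparator_types):
    """Per-gene ratio by explicit enumeration of every replicate value."""
    out = {}
    for gene in dataset.values.index:
        idx_vals = [
            dataset.values.at[gene, s.sample_id]
            for s in dataset.samples
            if s.cell_type in index_types
        ]
        cmp_vals = [
            dataset.values.at[gene, s.sample_id]
            for s in dataset.samples
            if s.cell_type in comparator_types
        ]
        out[gene] = min(idx_vals) / max(cmp_vals)
    return out


def brute_upgma(dist: pd.DataFrame):
    """O(n^3) UPGMA returning merge heights and the merged leaf sets."""
    labels = list(dist.index)
    clusters: dict[frozenset, list[str]] = {frozenset([l]): [l] for l in labels}
    d = {
        (frozenset([a]), frozenset([b])): float(dist.at[a, b])
        for a, b in itertools.combinations(labels, 2)
    }

    def get(a, b):
        return d.get((a, b), d.get((b, a)))

    merges = []
    while len(clusters) > 1:
        pair = min(
            itertools.combinations(clusters, 2),
            key=lambda ab: (get(*ab), sorted(map(sorted, ab))),
        )
        a, b = pair
        h = get(a, b)
        new = a | b
        merges.append((set(new), h))
        na, nb = len(clusters[a]), len(clusters[b])
        members = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        for other in list(clusters):
            dn = (get(a, other) * na + get(b, other) * nb) / (na + nb)
            d[(new, other)] = dn
        clusters[new] = members
    return merges
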