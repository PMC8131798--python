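"""Shared fixtures: hand-built pedigrees and reusable simulated studies."""

from __future__ import annotations

import numpy as np
import pytest

from spiderqg.pedigree import Pedigree


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records(
        [("dam", "NA", "NA", "f"), ("sire", "NA", "NA", "m"),
         ("kid", "dam", "sire", "f")]
    )


@pytest.fixture
def fullsib_inbred() -> Pedigree:
    """Two full sibs mated; their offspring has F = 0.25."""
    return Pedigree.from_records(
        [("d", "NA", "NA", "f"), ("s", "NA", "NA", "m"),
         ("a", "d", "s", "f"), ("b", "d", "s", "m"),
         ("x", "a", "b", "f")]
    )


def random_pedigree(n: int, seed: int, n_founders: int | None = None) -> Pedigree:
    """Random multi-generation pedigree for property tests.

    Parents of each non-founder are drawn from earlier individuals of the
    right sex, so inbreeding and deep relationships occur naturally.
    """
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(4, n // 5)
    recs = []
    sexes = []
    for i in range(n):
        sex = "f" if rng.random() < 0.5 or i == 0 else "m"
        if i == 1:
            sex = "m"  # guarantee at least one of each
        sexes.append(sex)
        ident = f"I{i:04d}"
        if i < n_founders:
            recs.append((ident, "NA", "NA", sex))
            continue
        females = [f"I{j:04d}" for j in range(i) if sexes[j] == "f"]
        males = [f"I{j:04d}" for j in range(i) if sexes[j] == "m"]
        dam = females[rng.integers(len(females))] if females else "NA"
        sire = males[rng.integers(len(males))] if males else "NA"
        recs.append((ident, dam, sire, sex))
    return Pedigree.from_records(recs)


def gene_drop_relationship(
    ped: Pedigree, n_drops: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo additive relationships by gene dropping.

    Each founder gets two unique alleles; alleles are transmitted down the
    pedigree with independent fair Mendelian picks per replicate.  The
    additive relationship A(i,j) is estimated as twice the probability that
    a random allele of i is identical by descent to a random allele of j,
    i.e. the mean IBD-sharing over the four allele pairings, times two.
    Returns (A_hat, MC standard error matrix).
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    # allele ids: (n_drops, n, 2)
    alleles = np.empty((n_drops, n, 2), dtype=np.int64)
    next_founder_allele = 0
    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        if d >= 0:
            pick = rng.integers(0, 2, size=n_drops)
            alleles[:, i, 0] = alleles[np.arange(n_drops), d, pick]
        else:
            alleles[:, i, 0] = next_founder_allele
            next_founder_allele += 1
        if s >= 0:
            pick = rng.integers(0, 2, size=n_drops)
            alleles[:, i, 1] = alleles[np.arange(n_drops), s, pick]
        else:
            alleles[:, i, 1] = next_founder_allele
            next_founder_allele += 1
    A = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            share = np.zeros(n_drops)
            for u in range(2):
                for v in range(2):
                    share += alleles[:, i, u] == alleles[:, j, v]
            kin2 = share / 2.0  # 2 * (mean IBD over 4 pairings)
            A[i, j] = A[j, i] = kin2.mean()
            se[i, j] = se[j, i] = kin2.std(ddof=1) / np.sqrt(n_drops)
    return A, se
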