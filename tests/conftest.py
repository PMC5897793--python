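import numpy as np
import pytest

from orfscreen import (AlignmentHit, GeneratorProfile, HitSet, LabeledSample,
                       QueryProtein, extract_features, generate,
                       generate_benchmark)
from orfscreen.searchio import ungapped


def make_hit(q_aln: str, s_aln: str, *, query_id: str = "q",
             subject_id: str = "s", evalue: float = 1e-5,
             genetic_code: int = 11) -> tuple[AlignmentHit, QueryProtein]:
    """Build a coordinate-consistent hit (and its query) from aligned
    strings: the query is exactly the ungapped query string."""
    qseq = ungapped(q_aln)
    n_s = len(s_aln) - s_aln.count("-")
    hit = AlignmentHit(
        query_id=query_id, subject_id=subject_id, evalue=evalue,
        q_start=1, q_end=len(qseq), s_start=1, s_end=3 * n_s,
        q_aln=q_aln, s_aln=s_aln, genetic_code=genetic_code)
    query = QueryProtein(id=query_id, sequence=qseq)
    hit.validate(query)
    return hit, query


def random_alignment(rng: np.random.Generator, n_cols: int
                     ) -> tuple[str, str]:
    """Random aligned string pair with no dual-gap columns, >=1 residue
    on each side."""
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    while True:
        q_chars, s_chars = [], []
        for _ in range(n_cols):
            kind = rng.random()
            q = str(rng.choice(aas))
            s = str(rng.choice(aas + ["*"] * 4))
            if kind < 0.08:
                q = "-"
            elif kind < 0.16:
                s = "-"
            q_chars.append(q)
            s_chars.append(s)
        q_aln, s_aln = "".join(q_chars), "".join(s_chars)
        if ungapped(q_aln) and ungapped(s_aln):
            return q_aln, s_aln


def samples_from_dataset(dataset) -> list[LabeledSample]:
    return [LabeledSample(extract_features(hs), dataset.labels[hs.query.id],
                          hs.query.id)
            for hs in dataset.hitsets()]


@pytest.fixture(scope="session")
def bench30():
    """Small balanced benchmark shared across test modules."""
    return generate_benchmark(30, seed=1)


@pytest.fixture(scope="session")
def bench30_samples(bench30):
    return samples_from_dataset(bench30)


@pytest.fixture(scope="session")
def spurious12():
    """One neutrally-evolving spurious query with 12 homologs (seed 7)."""
    d = generate(GeneratorProfile(regime="spurious_neutral", n_homologs=12,
                                  query_length_aa=90, subst_rate=0.3,
                                  indel_rate=0.03, seed=7))
    return d


@pytest.fixture(scope="session")
def spurious12_hitset(spurious12) -> HitSet:
    return spurious12.hitsets()[0]
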