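import numpy as np
import pytest

from nanomap import digest as digest_mod
from nanomap import simulate
from nanomap.models import DigestParams


@pytest.fixture(scope="session")
def small_genome():
    """A 500 kb synthetic genome at the default label density."""
    return simulate.simulate_genome(500_000, seed=101)


@pytest.fixture(scope="session")
def small_digest(small_genome):
    return digest_mod.digest_sequences([small_genome], DigestParams())


def scrubbed_sequence(length: int, motifs, seed: int) -> str:
    """Random sequence with every motif occurrence destroyed (both strands).

    Lets tests plant an exact number of motif copies and know the digest
    count in advance. ``motifs`` may be one motif or a list.
    """
    if isinstance(motifs, str):
        motifs = [motifs]
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    text = "".join(rng.choice(bases, size=length))
    patterns = []
    for motif in motifs:
        patterns += [motif, digest_mod.reverse_complement(motif)]
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    while True:
        hits = []
        for pat in patterns:
            start = 0
            while True:
                i = text.find(pat, start)
                if i < 0:
                    break
                hits.append((i, len(pat)))
                start = i + 1
        if not hits:
            return text
        chars = list(text)
        for h, m in hits:
            chars[h + m // 2] = flip[chars[h + m // 2]]
        text = "".join(chars)


def plant_motifs(sequence: str, motif: str, positions) -> str:
    chars = list(sequence)
    for p in positions:
        chars[p:p + len(motif)] = list(motif)
    return "".join(chars)
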