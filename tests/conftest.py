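import random
import string

import numpy as np
import pytest

from gapstitch.chem import WATER, residue_mass, reverse
from gapstitch.params import Params
from gapstitch.tagging import Tag, TagSet

ALPHABET = "ACDEFGHKLMNPQRSTVWY"  # I folded into L


@pytest.fixture(scope="session")
def params() -> Params:
    return Params()


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(length))


def ideal_tagset(
    protein: str, n_spectra: int = 5, k: int = 4, with_reversed: bool = True
) -> TagSet:
    """Noise-free tags constructed directly from prefix/suffix residue sums.

    Independent of the spectrum-graph pipeline: every k-residue window of the
    protein yields a forward tag at the prefix-mass offset, and (optionally)
    a reversed tag at the water + suffix-mass offset, in every spectrum.
    """
    prefix = [0.0]
    for aa in protein:
        prefix.append(prefix[-1] + residue_mass(aa))
    total = prefix[-1]
    tagset = TagSet()
    for s in range(n_spectra):
        sid = f"ideal{s}"
        for i in range(len(protein) - k + 1):
            tagset.add(Tag(protein[i : i + k], prefix[i], sid))
            if with_reversed:
                offset = WATER + (total - prefix[i + k])
                tagset.add(Tag(reverse(protein[i : i + k]), offset, sid))
    return tagset


def random_tagset(
    rng: random.Random, strings: list[str], k: int = 4, n_tags: int = 15, n_spectra: int = 3
) -> TagSet:
    """Tags with sequences drawn from the k-mers of *strings* (and their
    reverses) plus occasional unrelated k-mers, at random offsets."""
    kmers = []
    for s in strings:
        for i in range(len(s) - k + 1):
            kmers.append(s[i : i + k])
            kmers.append(reverse(s[i : i + k]))
    tagset = TagSet()
    for _ in range(n_tags):
        if kmers and rng.random() < 0.8:
            seq = rng.choice(kmers)
        else:
            seq = "".join(rng.choice(ALPHABET) for _ in range(k))
        offset = round(rng.uniform(0, 5000), 4)
        tagset.add(Tag(seq, offset, f"spec{rng.randrange(n_spectra)}"))
    return tagset
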