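"""Seeded random protein sequences for tests."""

import numpy as np

from plantloc.seqio import AA_ALPHABET


def random_protein(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA_ALPHABET), size=length))
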