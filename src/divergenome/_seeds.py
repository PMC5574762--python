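"""Deterministic seed derivation.

Every stage of the pipeline draws its random seed from a master seed and a
tuple of string/int keys identifying the unit of work (scenario, replicate,
pair, stage).  Seeds are derived by hashing, not by incrementing a counter,
so adding scenarios, replicates or pairs never perturbs the seeds of
existing ones and any subset of the experiment can be rerun identically.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, *keys: object) -> int:
    """Derive a stage seed in [1, 2**31 - 2] from a master seed and keys.

    The same (master_seed, keys) always yields the same seed; distinct key
    tuples collide with probability ~2**-31.  The result is strictly
    positive, as required by msprime.
    """
    token = ":".join([str(int(master_seed))] + [str(k) for k in keys])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % (2**31 - 2) + 1
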