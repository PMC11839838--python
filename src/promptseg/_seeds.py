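"""Stable sub-seed derivation: no global RNG state anywhere in the package."""

import hashlib


def derive_seed(*tokens) -> int:
    """Derive a reproducible 31-bit seed from arbitrary hashable tokens.

    Uses SHA-256 of the ``repr`` of the token tuple, so the mapping is stable
    across processes and platforms (unlike ``hash()``).
    """
    digest = hashlib.sha256(repr(tokens).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
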