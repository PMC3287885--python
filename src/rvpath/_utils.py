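"""Shared plumbing: errors, RNG derivation."""

from __future__ import annotations

import zlib

import numpy as np


class RvPathError(Exception):
    """Base class for all package errors."""


class ParseError(RvPathError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(RvPathError):
    """Input violated a documented invariant or precondition."""


class UnsupportedRecordError(RvPathError):
    """A record uses a feature the toolkit deliberately does not handle."""


def _key_to_int(key) -> int:
    """Stable 31-bit integer from an arbitrary hashable key."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf-8")) & 0x7FFFFFFF


def derived_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-unit random stream.

    One master seed drives the whole pipeline; subordinate streams are
    derived from (seed, *keys) so results do not depend on the order in
    which units are processed.
    """
    entropy = [_key_to_int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
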