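"""Plain-text profile I/O with lossless round-tripping."""

from __future__ import annotations

import numpy as np

from .dose import DepthProfile

PROFILE_HEADER = "depth_cm,value"


class ProfileFormatError(ValueError):
    pass


def write_profile(path, profile: DepthProfile) -> None:
    with open(path, "w") as fh:
        fh.write(PROFILE_HEADER + "\n")
        for d, v in zip(profile.depth, profile.value):
            fh.write(f"{float(d)!r},{float(v)!r}\n")


def read_profile(path) -> DepthProfile:
    depths, values = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != PROFILE_HEADER:
            raise ProfileFormatError(
                f"bad header {header!r}; expected {PROFILE_HEADER!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cols = line.split(",")
            if len(cols) != 2:
                raise ProfileFormatError(f"line {lineno}: expected 2 columns")
            try:
                depths.append(float(cols[0]))
                values.append(float(cols[1]))
            except ValueError as exc:
                raise ProfileFormatError(f"line {lineno}: {exc}") from exc
    return DepthProfile(np.asarray(depths), np.asarray(values))
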