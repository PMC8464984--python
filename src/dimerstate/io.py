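"""Plain-text readers and writers for photon streams and scattering curves.

Photon stream format: tab-separated ``timestamp_s  excitation  channel`` rows
(tags 'D'/'A') preceded by ``# key=value`` metadata header lines.  SAXS
format: the common whitespace-separated 3-column ``q I sigma`` dialect with
``#`` comments.  Both round-trip losslessly at full float precision.
"""

from __future__ import annotations

import ast
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataFormatError
from .saxs import SaxsCurve
from .simulate import PhotonStream

__all__ = ["write_photon_stream", "read_photon_stream", "write_saxs", "read_saxs"]

log = logging.getLogger("dimerstate")


def _format_meta_value(v):
    return repr(v) if isinstance(v, (dict, list, tuple)) else str(v)


def _parse_meta_value(s: str):
    try:
        return ast.literal_eval(s)
    except (ValueError, SyntaxError):
        return s


def write_photon_stream(stream: PhotonStream, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# dimerstate photon stream v1\n")
        for key, val in stream.meta.items():
            if key == "species":
                continue  # nested structures stay out of the flat header
            fh.write(f"# {key}={_format_meta_value(val)}\n")
        fh.write("# columns=timestamp_s\texcitation\tchannel\n")
        df = pd.DataFrame(
            {
                "t": stream.timestamps,
                "exc": stream.excitation,
                "ch": stream.channel,
            }
        )
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.17g")


def read_photon_stream(path) -> PhotonStream:
    """Parse a photon stream file; sorts unsorted timestamps with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"photon stream file not found: {path}")
    meta: dict = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = _parse_meta_value(val.strip())
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["t", "exc", "ch"],
            dtype={"t": float, "exc": str, "ch": str},
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"{path}: malformed photon table: {exc}") from exc
    if df.empty:
        return PhotonStream(np.empty(0), np.empty(0, "U1"), np.empty(0, "U1"), meta=meta)
    bad = ~df["exc"].isin(["D", "A"]) | ~df["ch"].isin(["D", "A"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataFormatError(
            f"{path}: invalid excitation/channel tag at line {n_header + row + 1}"
        )
    t = df["t"].to_numpy()
    exc = df["exc"].to_numpy(dtype="U1")
    ch = df["ch"].to_numpy(dtype="U1")
    if np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: timestamps not sorted; sorting on read", stacklevel=2)
        log.warning("%s: timestamps not sorted; sorting on read", path)
        order = np.argsort(t, kind="stable")
        t, exc, ch = t[order], exc[order], ch[order]
    meta.pop("columns", None)
    return PhotonStream(t, exc, ch, meta=meta)


def write_saxs(curve: SaxsCurve, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# dimerstate SAXS curve: q [1/A]  I [a.u.]  sigma\n")
        for key, val in curve.meta.items():
            fh.write(f"# {key}={_format_meta_value(val)}\n")
        for q, i, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{q:.17g} {i:.17g} {s:.17g}\n")


def read_saxs(curve_path, sigma_floor_rel: float = 1e-6) -> SaxsCurve:
    """Read a 3-column ``q I sigma`` file.

    Fewer than three columns is an error (a missing sigma column is never
    silently defaulted).  Non-ascending q is sorted with a warning;
    nonpositive sigmas are replaced by ``sigma_floor_rel * max |I|`` with a
    warning.  ``#`` comment lines are preserved as metadata.
    """
    path = Path(curve_path)
    if not path.exists():
        raise FileNotFoundError(f"SAXS file not found: {path}")
    meta: dict = {}
    comments: list[str] = []
    rows = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            body = line.strip()
            if not body:
                continue
            if body.startswith("#"):
                text = body[1:].strip()
                if "=" in text:
                    key, _, val = text.partition("=")
                    meta[key.strip()] = _parse_meta_value(val.strip())
                else:
                    comments.append(text)
                continue
            parts = body.split()
            if len(parts) < 3:
                raise DataFormatError(
                    f"{path}: line {ln}: expected >= 3 columns (q I sigma), got {len(parts)}"
                )
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise DataFormatError(f"{path}: line {ln}: non-numeric value") from exc
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    arr = np.asarray(rows)
    q, I, sigma = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(np.diff(q) <= 0):
        warnings.warn(f"{path}: q not strictly ascending; sorting", stacklevel=2)
        order = np.argsort(q, kind="stable")
        q, I, sigma = q[order], I[order], sigma[order]
        keep = np.concatenate([[True], np.diff(q) > 0])
        q, I, sigma = q[keep], I[keep], sigma[keep]
    if np.any(sigma <= 0):
        floor = sigma_floor_rel * float(np.abs(I).max())
        warnings.warn(f"{path}: nonpositive sigma replaced by floor {floor:g}", stacklevel=2)
        sigma = np.where(sigma <= 0, floor, sigma)
    if comments:
        meta["comments"] = comments
    return SaxsCurve(q, I, sigma, meta=meta)
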