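"""Minimal Bruker-style 2D time-domain reader/writer.

Supported on-disk dialect: an experiment directory holding

* ``ser``     — the 2D time-domain grid, direct dimension fastest, each
  complex point stored as interleaved (real, imag);
* ``acqus``   — direct-dimension parameters (JCAMP-DX style ``##$KEY= value``
  lines): TD (real+imag point count), SW_h, O1, SFO1, BYTORDA
  (0 little / 1 big endian), DTYPA (0 int32 / 2 float64), GRPDLY;
* ``acqu2s``  — indirect-dimension parameters: TD (increment count), SW_h.

Rows padded to 1 KiB blocks (as written by some acquisition software for
int32 data) are detected from the file size and handled.  A positive group
delay (the digital filter's dead time) is removed by a circular time shift
implemented as an FT-domain phase ramp, which is exact for fractional
delays.  Frequencies are referenced to the carrier (O1 is stored for ppm
display only).

The writer emits the same dialect (float64, little-endian, no padding,
GRPDLY 0) and round-trips bit-exactly; it exists for interchange and for
testing the reader, not as a vendor-faithful exporter.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import ExpInfo, FID2D

__all__ = ["read_bruker_2d", "write_bruker_2d", "read_params"]

_PARAM_RE = re.compile(r"^##\$?(.+?)=\s*(.*)$")


def read_params(path: Path) -> dict[str, str]:
    """Parse ``##$KEY= value`` lines of a JCAMP-DX-style parameter file."""
    params: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        m = _PARAM_RE.match(line.strip())
        if m:
            params[m.group(1)] = m.group(2).strip()
    return params


def _require(params: dict[str, str], key: str, path: Path) -> str:
    if key not in params:
        raise ValueError(f"parameter {key} missing from {path}")
    return params[key]


def _remove_group_delay(data: np.ndarray, grpdly: float) -> np.ndarray:
    """Advance every direct-dimension slice by ``grpdly`` samples (circular)."""
    n2 = data.shape[1]
    k = np.fft.fftfreq(n2) * n2
    ramp = np.exp(2j * np.pi * k * grpdly / n2)
    return np.fft.ifft(np.fft.fft(data, axis=1) * ramp[None, :], axis=1)


def read_bruker_2d(path: str | Path) -> FID2D:
    """Read a 2D time-domain experiment directory into an :class:`FID2D`."""
    path = Path(path)
    acqus_p, acqu2s_p, ser_p = path / "acqus", path / "acqu2s", path / "ser"
    for p in (acqus_p, acqu2s_p, ser_p):
        if not p.exists():
            raise FileNotFoundError(f"required file missing: {p}")
    acqus = read_params(acqus_p)
    acqu2s = read_params(acqu2s_p)
    td2 = int(_require(acqus, "TD", acqus_p))
    n1 = int(_require(acqu2s, "TD", acqu2s_p))
    if td2 % 2:
        raise ValueError(f"direct-dimension TD must be even (real+imag), got {td2}")
    n2 = td2 // 2
    sw2 = float(_require(acqus, "SW_h", acqus_p))
    sw1 = float(_require(acqu2s, "SW_h", acqu2s_p))
    byteorder = "<" if int(acqus.get("BYTORDA", "0")) == 0 else ">"
    dtypa = int(acqus.get("DTYPA", "0"))
    if dtypa == 0:
        dtype = np.dtype(byteorder + "i4")
    elif dtypa == 2:
        dtype = np.dtype(byteorder + "f8")
    else:
        raise ValueError(f"unknown data encoding DTYPA={dtypa} (supported: 0 int32, 2 float64)")
    raw = np.fromfile(ser_p, dtype=dtype)
    row_vals = td2
    if raw.size != n1 * row_vals:
        # 1 KiB row padding
        pad_vals = -(-row_vals * dtype.itemsize // 1024) * 1024 // dtype.itemsize
        if raw.size == n1 * pad_vals:
            raw = raw.reshape(n1, pad_vals)[:, :row_vals].ravel()
        else:
            raise ValueError(
                f"ser size mismatch: expected {n1 * row_vals} values "
                f"({n1} x {row_vals}, or padded {n1 * pad_vals}), found {raw.size}"
            )
    vals = raw.astype(np.float64).reshape(n1, n2, 2)
    data = vals[..., 0] + 1j * vals[..., 1]
    grpdly = float(acqus.get("GRPDLY", "0") or 0.0)
    if grpdly > 0:
        data = _remove_group_delay(data, grpdly)
    sfo = float(acqus["SFO1"]) if "SFO1" in acqus else None
    o1 = float(acqus.get("O1", "0"))
    o1_1 = float(acqu2s.get("O1", "0"))
    info = ExpInfo(
        points=(n1, n2),
        dwell=(1.0 / sw1, 1.0 / sw2),
        offset=(o1_1, o1),
        sfo=sfo,
    )
    return FID2D(data, info)


def write_bruker_2d(fid: FID2D, path: str | Path) -> Path:
    """Write an :class:`FID2D` in the supported dialect (see module docs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n1, n2 = fid.expinfo.points
    sw1, sw2 = fid.expinfo.sweep_widths
    lines2 = [
        "##TITLE= synthetic 2DJ time-domain data",
        f"##$TD= {2 * n2}",
        f"##$SW_h= {sw2!r}",
        f"##$O1= {fid.expinfo.offset[1]!r}",
        "##$BYTORDA= 0",
        "##$DTYPA= 2",
        "##$GRPDLY= 0",
    ]
    if fid.expinfo.sfo is not None:
        lines2.append(f"##$SFO1= {fid.expinfo.sfo!r}")
    (path / "acqus").write_text("\n".join(lines2) + "\n")
    lines1 = [
        "##TITLE= synthetic 2DJ time-domain data, indirect dimension",
        f"##$TD= {n1}",
        f"##$SW_h= {sw1!r}",
        f"##$O1= {fid.expinfo.offset[0]!r}",
    ]
    (path / "acqu2s").write_text("\n".join(lines1) + "\n")
    out = np.empty((n1, n2, 2), dtype="<f8")
    out[..., 0] = fid.data.real
    out[..., 1] = fid.data.imag
    out.tofile(path / "ser")
    return path
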