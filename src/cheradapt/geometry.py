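"""Geometry of the receptor methylation sites and the CheR tether.

The four modifiable glutamates of a Tar monomer sit on two parallel
alpha-helices; CheR docks at the C-terminal pentapeptide (NWETF) reached
through a flexible chain of 34 residues in wild-type Tar.  Each residue of
an alpha-helix advances 0.15 nm along the helical axis, which sets the
distance R of each site from the tethering point, and each residue of the
fully extended flexible chain contributes a peptide-bond length of 0.36 nm
to the tether contour length.

Methylation proceeds sequentially (site #3 -> #2 -> #1 -> #4), so the
methylation level m = 1..4 maps onto a distance R(m) that is well described
by a straight line R = k*m + R0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PEPTIDE_BOND_NM",
    "HELIX_RISE_NM",
    "PENTAPEPTIDE",
    "SiteGeometry",
    "ChainConstruct",
    "TAR_CONSTRUCTS",
    "contour_length",
    "tar_site_distances",
    "tar_site_geometry",
    "tsr_site_distances",
    "LinearFit",
    "fit_R_of_m",
    "count_tether_residues",
    "read_tether_fasta",
    "geometry_table",
]

PEPTIDE_BOND_NM = 0.36  # contour contribution per residue of the tether
HELIX_RISE_NM = 0.15  # axial translation per residue of an alpha-helix
PENTAPEPTIDE = "NWETF"  # CheR docking motif at the extreme C-terminus

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SiteGeometry:
    """One modifiable site: label, order of methylation, distance from tether."""

    site_label: str  # "#1".."#4" for Tar, "#1".."#5" for Tsr
    methylation_order: int  # 1-based position in the sequential order
    distance_R: float  # nm from the tethering point

    def __post_init__(self) -> None:
        if self.distance_R <= 0:
            raise ValueError("site distance must be > 0")


@dataclass(frozen=True)
class ChainConstruct:
    """A tether construct: residue count and derived contour length."""

    name: str
    n_residues: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise ValueError("residue count must be > 0")
        if self.sequence is not None:
            n = count_tether_residues(self.sequence)
            if n != self.n_residues:
                raise ValueError(
                    f"sequence of {self.name} counts {n} tether residues, "
                    f"expected {self.n_residues}")

    @property
    def L_total(self) -> float:
        """Contour length in nm (residues x 0.36 nm)."""
        return contour_length(self.n_residues)


def contour_length(n_residues: int) -> float:
    """Contour length of a fully extended tether: n_residues x 0.36 nm."""
    if n_residues <= 0:
        raise ValueError("residue count must be > 0")
    return n_residues * PEPTIDE_BOND_NM


def count_tether_residues(sequence: str) -> int:
    """Count tether residues in an amino-acid string.

    The terminal pentapeptide NWETF (the CheR docking site) is excluded:
    the tether is the stretch between the receptor body and the docking
    motif.  Dashes mark deletions and are skipped, as is whitespace.
    """
    seq = "".join(sequence.split()).upper()
    seq = seq.replace("-", "")
    if not seq:
        raise ValueError("empty tether sequence")
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non amino-acid characters in sequence: {sorted(bad)}")
    if seq.endswith(PENTAPEPTIDE):
        seq = seq[: -len(PENTAPEPTIDE)]
    if not seq:
        raise ValueError("sequence contains only the pentapeptide")
    return len(seq)


#: Tether constructs with their chain sequences (pentapeptide included).
TAR_CONSTRUCTS: Dict[str, ChainConstruct] = {
    "pLC113": ChainConstruct(
        "pLC113", 34, "LAASPLTNKPQTPSRPASEQPPAQPRLRIAEQDPNWETF"),
    "pCZ1": ChainConstruct(
        "pCZ1", 29, "LAASPLTNKPQTPSRPASEQPPAQPRLRI---------NWETF"),
    "pCZ2": ChainConstruct(
        "pCZ2", 22, "LAASPLTNKPQTPSRPASEQPP----------------------NWETF"),
    "pCZ4": ChainConstruct(
        "pCZ4", 46, "LAASPLTNKPQTPSRPASEQPPAQPRLRIAEQDPAPRKMAVADSEENWETF"),
    "Tsr": ChainConstruct(
        "Tsr", 30, "IQQQQRETSAVVKTVTPAAPRKMAVADSEENWETF"),
}


# Distances of Tar sites from the tethering residue R514, in sequential
# methylation order #3 -> #2 -> #1 -> #4.  Site #4 (E491) lies 23 residues
# from R514 on the tether helix: 23 x 0.15 nm = 3.45 nm.
_TAR_SITES = (
    SiteGeometry("#3", 1, 6.75),
    SiteGeometry("#2", 2, 5.70),
    SiteGeometry("#1", 3, 4.65),
    SiteGeometry("#4", 4, 3.45),
)

# Tsr site distances from the tethering residue R516, printed order.
_TSR_DISTANCES = (4.95, 6.0, 7.05, 3.45, 2.1)


def tar_site_geometry() -> Tuple[SiteGeometry, ...]:
    """The four Tar sites with labels, methylation order and distances."""
    return _TAR_SITES


def tar_site_distances() -> Dict[int, float]:
    """Map methylation order m = 1..4 to site distance R (nm) for Tar."""
    return {s.methylation_order: s.distance_R for s in _TAR_SITES}


def tsr_site_distances() -> List[float]:
    """Distances of the five Tsr methylation sites from the tether (nm)."""
    return list(_TSR_DISTANCES)


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line fit with standard errors."""

    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    r_value: float


def fit_R_of_m(points: Sequence[Tuple[float, float]]) -> LinearFit:
    """OLS fit of the site distance against methylation order, R = k*m + R0.

    Needs at least two distinct m values; degenerate designs are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (m, R) pairs")
    m, R = pts[:, 0], pts[:, 1]
    if np.unique(m).size < 2:
        raise ValueError("degenerate design: all m values identical")
    res = stats.linregress(m, R)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
        r_value=float(res.rvalue),
    )


def read_tether_fasta(path: Union[str, Path]) -> Dict[str, int]:
    """Read tether sequences from FASTA; return residue counts per record."""
    from Bio import SeqIO

    counts: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        counts[rec.id] = count_tether_residues(str(rec.seq))
    if not counts:
        raise ValueError(f"no FASTA records found in {path}")
    return counts


def geometry_table(receptor: str = "tar") -> pd.DataFrame:
    """Site-geometry table (order, site_label, R_nm) for CSV export."""
    if receptor.lower() == "tar":
        rows = [(s.methylation_order, s.site_label, s.distance_R)
                for s in _TAR_SITES]
    elif receptor.lower() == "tsr":
        rows = [(i + 1, f"site{i + 1}", R)
                for i, R in enumerate(_TSR_DISTANCES)]
    else:
        raise ValueError(f"unknown receptor {receptor!r}")
    return pd.DataFrame(rows, columns=["order", "site_label", "R_nm"])
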