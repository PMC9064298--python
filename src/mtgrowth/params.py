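"""Kinetic and thermodynamic parameters of the protofilament lattice model.

All rates are in s^-1, bimolecular rate constants in uM^-1 s^-1,
dissociation constants in uM, lengths in nm, times in s.
"""
from __future__ import annotations

import dataclasses
import io
import pathlib

import yaml

#: Axial length of one alpha/beta-tubulin dimer (nm).
DIMER_LENGTH_NM = 8.2

#: Protofilaments in the canonical microtubule wall.
N_PF = 13


@dataclasses.dataclass
class ModelParams:
    """Parameters of the kinetic lattice model of microtubule elongation.

    The model represents the microtubule as 13 protofilaments growing by
    single-dimer association and dissociation.  Association onto each
    protofilament end occurs at ``k_on * tubulin_conc``; dissociation of a
    terminal subunit occurs at ``k_on * K_D`` where ``K_D`` follows from the
    contacts the subunit makes.  Free energies of longitudinal and lateral
    contacts add, so a site with ``n`` lateral neighbours has

        ``K_D = K_D_long * (K_D_corner / K_D_long) ** n``

    The nucleotide (GTP or GDP) acts in trans: the nucleotide bound to the
    *lower* subunit of a longitudinal interface sets that interface's
    strength, and a GDP interface is weaker by the factor ``gdp_factor_X``.
    """

    k_on: float = 0.74            # uM^-1 s^-1, bimolecular association rate constant
    K_D_long: float = 87.0        # uM, pure longitudinal contact (GTP interface)
    K_D_corner: float = 0.025     # uM, corner site: one longitudinal + one lateral
    tubulin_conc: float = 1.5     # uM free alpha/beta-tubulin
    k_GTPase: float = 0.0         # s^-1, hydrolysis rate per eligible subunit
    gdp_factor_X: float = 1.0     # dimensionless weakening of a GDP longitudinal interface
    site_dependent_kon: bool = False
    kon_ratio_long_corner: float = 1.67   # k_on(long) / k_on(corner)
    kon_ratio_corner_bucket: float = 4.62  # k_on(corner) / k_on(bucket)
    n_pf: int = N_PF
    dimer_length: float = DIMER_LENGTH_NM  # nm
    seam_offset: int = 2          # dimer stagger of lateral contacts across the seam

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.K_D_long <= 0 or self.K_D_corner <= 0:
            raise ValueError("rate constants and affinities must be strictly positive")
        if self.tubulin_conc < 0:
            raise ValueError("tubulin concentration must be non-negative")
        if self.k_GTPase < 0:
            raise ValueError("k_GTPase must be non-negative")
        if self.gdp_factor_X < 1:
            raise ValueError("gdp_factor_X must be >= 1")
        if self.K_D_corner >= self.K_D_long:
            raise ValueError("K_D_corner must be smaller than K_D_long")
        if self.n_pf < 2:
            raise ValueError("need at least two protofilaments")

    @property
    def lateral_ratio(self) -> float:
        """Multiplicative affinity gain per lateral contact (dimensionless)."""
        return self.K_D_corner / self.K_D_long

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    # -- parameter files ---------------------------------------------------
    def to_file(self, path) -> None:
        """Write a ``key: value`` parameter file mirroring the field names."""
        d = dataclasses.asdict(self)
        pathlib.Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        if isinstance(path, io.IOBase):
            d = yaml.safe_load(path)
        else:
            d = yaml.safe_load(pathlib.Path(path).read_text())
        return cls(**d)


# Published best-fit parameter sets from the concentration-series fits.
GMPCPP_PARAMS = ModelParams(k_on=0.74, K_D_long=87.0, K_D_corner=0.025,
                            tubulin_conc=1.5)
GTP_PARAMS = ModelParams(k_on=0.74, K_D_long=1700.0, K_D_corner=2.9,
                         tubulin_conc=7.5)

#: Tubulin concentrations (uM) used in the two concentration series.
GMPCPP_CONCENTRATIONS = (0.5, 0.7, 1.1, 1.3, 1.5)
GTP_CONCENTRATIONS = (7.5, 10.0, 12.5, 15.0, 17.5)

#: Apparent growth-variance floor of the imaging assay measured on static
#: seeds (nm^2/s); added to simulated variances when comparing to experiment.
STATIC_SEED_NOISE_OFFSET = 0.97
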