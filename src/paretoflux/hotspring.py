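"""Hot-spring phototrophic mat community fixture (synthetic stand-in).

The fixture models three guilds -- SYN, a *Synechococcus*-like oxygenic
primary producer; FAP, filamentous anoxygenic phototrophs; and SRB,
sulfate-reducing bacteria -- linked through a shared pool: SYN fixes CO2
photosynthetically (with an obligate 0.03 oxygenase/carboxylase flux ratio
between ``RXN-961`` and ``RIBULOSE-BISPHOSPHATE-CARBOXYLASE-RXN`` diverting
carbon to glycolate), assimilates nitrate and exports surplus ammonia and
acetate, which are the consumers' only nitrogen and carbon sources.

The guild stoichiometries are a **synthetic stand-in**, not curated
genome-scale networks: each guild's biomass quotas and the community supply
caps (photons, nitrate, phosphate, sulfate) were calibrated analytically so
the community reproduces the benchmark behavior of the real mat model --
per-guild solo growth optima of 1 h^-1 and a five-vertex community Pareto
front with extreme points (1,0,0), (0,1,0), (0,0,1), (0.27,0,0.89) and
(0,0.46,0.65).  The thermodynamic table is likewise synthetic: potentials are
internally consistent on an arbitrary per-element reference, with the
photon potential anchored at 68.6 kJ/mol via the glucose-synthesis
equilibrium and dg = RT ln(10^3) ~ 20 kJ/mol at 75 C for all species except
fixed-concentration water and photons (dg = 0).
"""

from __future__ import annotations

from importlib import resources

from .community import CommunityModel, add_ratio_coupling, assemble_community, PoolSpec
from .core import ThermoTable
from .errors import ValidationError
from .io import read_strain_tabular, read_thermo_table

GUILDS = ("SYN", "FAP", "SRB")

#: oxygenase/carboxylase flux ratio imposed during all calculations
RUBISCO_OXYGENASE_RATIO = 0.03

#: photosynthesis reactions coupled by the ratio constraint
RUBISCO_RXN = "RIBULOSE-BISPHOSPHATE-CARBOXYLASE-RXN"
OXYGENASE_RXN = "RXN-961"

#: stoichiometry of the glucose-synthesis reaction used to anchor the photon
#: potential (photons excluded; 48 photons drive the reaction)
GLUCOSE_SYNTHESIS = {"CO2": -6.0, "H2O": -6.0, "GLC": 1.0}
GLUCOSE_SYNTHESIS_PHOTONS = 48.0


def _data_dir():
    return resources.files("paretoflux.data").joinpath("hotspring_synthetic")


def load_hotspring_fixture() -> tuple[CommunityModel, ThermoTable]:
    """Load the packaged 3-guild community and its thermodynamic table.

    Returns the assembled community (pool routing + 0.03 ratio coupling
    installed) and the thermo table.  Raises :class:`ValidationError` if the
    packaged data is missing -- never a silent fallback.
    """
    base = _data_dir()
    paths = {name: base.joinpath(f"{name.lower()}.tsv") for name in GUILDS}
    thermo_path = base.joinpath("thermo.tsv")
    pool_path = base.joinpath("pool.json")
    missing = [str(p) for p in [*paths.values(), thermo_path, pool_path]
               if not p.is_file()]
    if missing:
        raise ValidationError(
            "hot-spring supplementary data not encoded in this installation; "
            f"missing: {missing}"
        )
    strains = [read_strain_tabular(paths[name]) for name in GUILDS]
    import json

    pool_doc = json.loads(pool_path.read_text())
    pool = PoolSpec(
        shared=list(pool_doc["shared"]),
        env_exchange={m: (float(b[0]), float(b[1]))
                      for m, b in pool_doc["env_exchange"].items()},
    )
    community = assemble_community(strains, pool)
    add_ratio_coupling(
        community, "SYN", OXYGENASE_RXN, RUBISCO_RXN, RUBISCO_OXYGENASE_RATIO
    )
    thermo = read_thermo_table(thermo_path)
    return community, thermo
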