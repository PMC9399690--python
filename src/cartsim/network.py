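"""Reduced reaction network for CAR-triggered ERK activation.

The network compresses CAR signalling into six stages:

1. reversible CAR-antigen binding at the cell surface;
2. an LCK activity cycle (CSK-mediated inhibition, CD45-mediated
   reactivation of the inhibitory site);
3. LCK-catalysed ITAM phosphorylation of antigen-bound CAR, opposed by
   CD45 and by SHP1 recruited through phospho-ITAM (negative feedback);
4. ZAP70 docking on phospho-ITAM and phosphorylation of LAT;
5. SOS-mediated Ras-GDP -> Ras-GTP exchange driven by phospho-LAT (plus
   CD28-docked adaptor routes when enabled) against a constitutive GAP;
6. a Raf -> MEK -> ERK cascade with distributive dual phosphorylation at
   the MEK and ERK tiers, the source of the all-or-nothing ppERK switch.

States are concentrations in arbitrary units; time is in minutes; antigen
density enters as a constant input in molecules per square micron.

The network is stored as an explicit stoichiometry matrix plus a vector of
rate laws, so conservation laws are structural (left null space of the
stoichiometry matrix) and the same right-hand side evaluates a single cell
or a whole batch of cells with per-cell parameter vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constructs import CARConstruct
from .parameters import KineticParameterSet

SPECIES = [
    "CARf", "CARb", "CARbp1", "CARbp", "CARbp_ZAP",
    "LCKa", "LCK_CSK", "LCKi",
    "CSK", "CD45", "ZAP",
    "SHP1i", "SHP1a",
    "LAT", "LATp",
    "RasGDP", "RasGTP",
    "Raf", "Rafa",
    "MEK", "MEKp", "MEKpp",
    "ERK", "ERKp", "ERKpp",
]
_IX = {name: i for i, name in enumerate(SPECIES)}

#: Parameter order of the packed parameter vector theta.
PARAM_NAMES = [
    "kon_CAR", "koff_CAR",
    "Kcat_LCKPU_CD3z", "Km_LCK_CD3z",
    "Kcat_CD45_A1", "Km_CD45_A1",
    "Kcat_SHP1", "Km_SHP1", "k_SHP1_act", "k_SHP1_deact",
    "kon_ZAP", "koff_ZAP", "Kcat_ZAP", "Km_ZAP",
    "CSKon", "CSKoff", "kcat_CSK",
    "Kcat_CD45_LCK505", "Km_CD45_LCK505",
    "k_LATase",
    "k_SOS", "Km_LAT_SOS", "Km_Ras", "k_GAP",
    "k_Raf_act", "Km_Raf", "k_Raf_deact",
    "kcat_Raf_MEK", "Km_MEK", "Vmax_MEKase", "Km_MEKase",
    "kcat_MEK_ERK", "Km_ERK", "Vmax_ERKase", "Km_ERKase",
    "cd28_lck_boost", "cd28_dock_frac", "cd28_route_eff", "Km_CD28",
]
_PIX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: Committed initial totals (arbitrary concentration units).
DEFAULT_TOTALS = {
    "CAR": 30.0,
    "LCK": 100.0,
    "CSK": 60.0,
    "CD45": 60.0,
    "ZAP": 120.0,
    "SHP1": 60.0,
    "LAT": 150.0,
    "Ras": 120.0,
    "Raf": 100.0,
    "MEK": 200.0,
    "ERK": 200.0,
}

#: Conserved moieties: name -> member species (LCK_CSK counts in both the
#: LCK and CSK totals; the ZAP-occupied CAR counts in both CAR and ZAP70).
CONSERVED_MOIETIES = {
    "CAR": ["CARf", "CARb", "CARbp1", "CARbp", "CARbp_ZAP"],
    "LCK": ["LCKa", "LCK_CSK", "LCKi"],
    "CSK": ["LCK_CSK", "CSK"],
    "CD45": ["CD45"],
    "ZAP70": ["CARbp_ZAP", "ZAP"],
    "SHP1": ["SHP1i", "SHP1a"],
    "LAT": ["LAT", "LATp"],
    "Ras": ["RasGDP", "RasGTP"],
    "Raf": ["Raf", "Rafa"],
    "MEK": ["MEK", "MEKp", "MEKpp"],
    "ERK": ["ERK", "ERKp", "ERKpp"],
}

# (name, {species: net stoichiometry})
_REACTIONS = [
    ("CAR_bind", {"CARf": -1, "CARb": +1}),
    ("CAR_unbind", {"CARb": -1, "CARf": +1}),
    # ITAM tyrosines are phosphorylated distributively by LCK; doubly
    # phosphorylated ITAM is the ZAP70 docking site (tandem-SH2).
    ("ITAM_phos1_LCK", {"CARb": -1, "CARbp1": +1}),
    ("ITAM_phos2_LCK", {"CARbp1": -1, "CARbp": +1}),
    ("ITAM_dephos2_CD45", {"CARbp": -1, "CARbp1": +1}),
    ("ITAM_dephos1_CD45", {"CARbp1": -1, "CARb": +1}),
    ("ITAM_dephos2_SHP1", {"CARbp": -1, "CARbp1": +1}),
    ("ITAM_dephos1_SHP1", {"CARbp1": -1, "CARb": +1}),
    ("ZAP_bind", {"CARbp": -1, "ZAP": -1, "CARbp_ZAP": +1}),
    ("ZAP_unbind", {"CARbp_ZAP": -1, "CARbp": +1, "ZAP": +1}),
    ("LAT_phos", {"LAT": -1, "LATp": +1}),
    ("LAT_dephos", {"LATp": -1, "LAT": +1}),
    ("CSK_bind", {"LCKa": -1, "CSK": -1, "LCK_CSK": +1}),
    ("CSK_unbind", {"LCK_CSK": -1, "LCKa": +1, "CSK": +1}),
    ("LCK_inhibit", {"LCK_CSK": -1, "LCKi": +1, "CSK": +1}),
    ("LCK_reactivate", {"LCKi": -1, "LCKa": +1}),
    ("SHP1_activate", {"SHP1i": -1, "SHP1a": +1}),
    ("SHP1_deactivate", {"SHP1a": -1, "SHP1i": +1}),
    ("Ras_activate", {"RasGDP": -1, "RasGTP": +1}),
    ("Ras_deactivate", {"RasGTP": -1, "RasGDP": +1}),
    ("Raf_activate", {"Raf": -1, "Rafa": +1}),
    ("Raf_deactivate", {"Rafa": -1, "Raf": +1}),
    ("MEK_phos1", {"MEK": -1, "MEKp": +1}),
    ("MEK_phos2", {"MEKp": -1, "MEKpp": +1}),
    ("MEK_dephos2", {"MEKpp": -1, "MEKp": +1}),
    ("MEK_dephos1", {"MEKp": -1, "MEK": +1}),
    ("ERK_phos1", {"ERK": -1, "ERKp": +1}),
    ("ERK_phos2", {"ERKp": -1, "ERKpp": +1}),
    ("ERK_dephos2", {"ERKpp": -1, "ERKp": +1}),
    ("ERK_dephos1", {"ERKp": -1, "ERK": +1}),
]

REACTION_NAMES = [name for name, _ in _REACTIONS]


def _build_stoichiometry() -> np.ndarray:
    S = np.zeros((len(SPECIES), len(_REACTIONS)))
    for j, (_, stoich) in enumerate(_REACTIONS):
        for sp, coeff in stoich.items():
            S[_IX[sp], j] = coeff
    return S


STOICHIOMETRY = _build_stoichiometry()


class ModelAssemblyError(ValueError):
    """Raised when a network cannot be assembled from the given registry."""


@dataclass
class ReactionNetwork:
    """Assembled network: construct-specific rate laws over a fixed topology."""

    construct: CARConstruct
    theta: np.ndarray  # packed parameter vector, order PARAM_NAMES
    totals: dict[str, float]

    @property
    def n_species(self) -> int:
        return len(SPECIES)

    @property
    def species(self) -> list[str]:
        return SPECIES

    @property
    def stoichiometry(self) -> np.ndarray:
        return STOICHIOMETRY

    # ------------------------------------------------------------------
    def rates(self, x: np.ndarray, antigen, theta: np.ndarray | None = None) -> np.ndarray:
        """Reaction rate vector; x may be (24,) or (24, n), theta (39,) or (39, n)."""
        th = self.theta if theta is None else theta
        p = lambda name: th[_PIX[name]]
        s = lambda name: x[_IX[name]]
        con = self.construct

        kcat_lck = p("Kcat_LCKPU_CD3z")
        if con.generation == 2 and con.mech_lck_boost:
            kcat_lck = kcat_lck * p("cd28_lck_boost")

        CARb, CARbp1, CARbp, CARbpZ = s("CARb"), s("CARbp1"), s("CARbp"), s("CARbp_ZAP")
        pITAM = CARbp + CARbpZ

        # SOS activity: fraction phi of SOS docks on engaged CD28 when the
        # Grb2 / GADS routes are on (identical kinetics, hence symmetric),
        # feeding Ras with reduced efficiency; the rest reads phospho-LAT.
        n_adapt = 0
        if con.generation == 2:
            n_adapt = int(con.mech_grb2) + int(con.mech_gads)
        phi = n_adapt * p("cd28_dock_frac")
        LATp = s("LATp")
        sos = (1.0 - phi) * LATp / (p("Km_LAT_SOS") + LATp)
        if n_adapt:
            cd28b = CARb + CARbp1 + CARbp + CARbpZ  # engaged CD28 rides on bound CAR
            sos = sos + phi * p("cd28_route_eff") * cd28b / (p("Km_CD28") + cd28b)

        v = [
            p("kon_CAR") * antigen * s("CARf"),
            p("koff_CAR") * CARb,
            kcat_lck * s("LCKa") * CARb / (p("Km_LCK_CD3z") + CARb),
            kcat_lck * s("LCKa") * CARbp1 / (p("Km_LCK_CD3z") + CARbp1),
            p("Kcat_CD45_A1") * s("CD45") * CARbp / (p("Km_CD45_A1") + CARbp),
            p("Kcat_CD45_A1") * s("CD45") * CARbp1 / (p("Km_CD45_A1") + CARbp1),
            p("Kcat_SHP1") * s("SHP1a") * CARbp / (p("Km_SHP1") + CARbp),
            p("Kcat_SHP1") * s("SHP1a") * CARbp1 / (p("Km_SHP1") + CARbp1),
            p("kon_ZAP") * CARbp * s("ZAP"),
            p("koff_ZAP") * CARbpZ,
            p("Kcat_ZAP") * CARbpZ * s("LAT") / (p("Km_ZAP") + s("LAT")),
            p("k_LATase") * LATp,
            p("CSKon") * s("LCKa") * s("CSK"),
            p("CSKoff") * s("LCK_CSK"),
            p("kcat_CSK") * s("LCK_CSK"),
            p("Kcat_CD45_LCK505") * s("CD45") * s("LCKi") / (p("Km_CD45_LCK505") + s("LCKi")),
            p("k_SHP1_act") * pITAM * s("SHP1i"),
            p("k_SHP1_deact") * s("SHP1a"),
            p("k_SOS") * sos * s("RasGDP") / (p("Km_Ras") + s("RasGDP")),
            p("k_GAP") * s("RasGTP"),
            p("k_Raf_act") * s("RasGTP") * s("Raf") / (p("Km_Raf") + s("Raf")),
            p("k_Raf_deact") * s("Rafa"),
            p("kcat_Raf_MEK") * s("Rafa") * s("MEK") / (p("Km_MEK") + s("MEK")),
            p("kcat_Raf_MEK") * s("Rafa") * s("MEKp") / (p("Km_MEK") + s("MEKp")),
            p("Vmax_MEKase") * s("MEKpp") / (p("Km_MEKase") + s("MEKpp")),
            p("Vmax_MEKase") * s("MEKp") / (p("Km_MEKase") + s("MEKp")),
            p("kcat_MEK_ERK") * s("MEKpp") * s("ERK") / (p("Km_ERK") + s("ERK")),
            p("kcat_MEK_ERK") * s("MEKpp") * s("ERKp") / (p("Km_ERK") + s("ERKp")),
            p("Vmax_ERKase") * s("ERKpp") / (p("Km_ERKase") + s("ERKpp")),
            p("Vmax_ERKase") * s("ERKp") / (p("Km_ERKase") + s("ERKp")),
        ]
        return np.array(v) if x.ndim == 1 else np.stack(v)

    def rhs(self, t, x, antigen, theta: np.ndarray | None = None) -> np.ndarray:
        # clip tiny solver-induced negativity before rate evaluation
        x = np.where(x < 0, 0.0, x)
        return STOICHIOMETRY @ self.rates(x, antigen, theta)

    # ------------------------------------------------------------------
    def resting_state(self, theta: np.ndarray | None = None) -> np.ndarray:
        """No-antigen steady state.

        With zero antigen every phospho-species relaxes to zero; only the
        LCK / CSK / CD45 cycle has an interior steady state, found by
        bisection on active LCK. Works for (39,) or (39, n) theta.
        """
        th = self.theta if theta is None else theta
        p = lambda name: np.asarray(th[_PIX[name]], dtype=float)
        lck_tot = self.totals["LCK"]
        csk_tot = self.totals["CSK"]
        cd45 = self.totals["CD45"]

        cskon, cskoff, kcat = p("CSKon"), p("CSKoff"), p("kcat_CSK")
        vmax = p("Kcat_CD45_LCK505") * cd45
        km = p("Km_CD45_LCK505")

        def residual(a):
            c = cskon * a * csk_tot / (cskoff + kcat + cskon * a)
            flux = kcat * c
            # inhibited pool balancing the inhibition flux; cap at "all LCK"
            with np.errstate(divide="ignore", invalid="ignore"):
                i = np.where(flux < vmax, flux * km / np.maximum(vmax - flux, 1e-300), np.inf)
            i = np.minimum(i, 10.0 * lck_tot)
            return a + c + i - lck_tot

        scalar = np.ndim(p("CSKon")) == 0
        lo = np.zeros_like(vmax, dtype=float) + 1e-12
        hi = np.full_like(vmax, float(lck_tot), dtype=float)
        for _ in range(80):  # bisection: residual is increasing in a
            mid = 0.5 * (lo + hi)
            r = residual(mid)
            lo = np.where(r < 0, mid, lo)
            hi = np.where(r < 0, hi, mid)
        a = 0.5 * (lo + hi)
        c = cskon * a * csk_tot / (cskoff + kcat + cskon * a)
        i = np.maximum(lck_tot - a - c, 0.0)

        shape = () if scalar else a.shape
        x0 = np.zeros((len(SPECIES),) + shape)
        x0[_IX["CARf"]] = self.totals["CAR"]
        x0[_IX["LCKa"]] = a
        x0[_IX["LCK_CSK"]] = c
        x0[_IX["LCKi"]] = i
        x0[_IX["CSK"]] = csk_tot - c
        x0[_IX["CD45"]] = cd45
        x0[_IX["ZAP"]] = self.totals["ZAP"]
        x0[_IX["SHP1i"]] = self.totals["SHP1"]
        x0[_IX["LAT"]] = self.totals["LAT"]
        x0[_IX["RasGDP"]] = self.totals["Ras"]
        x0[_IX["Raf"]] = self.totals["Raf"]
        x0[_IX["MEK"]] = self.totals["MEK"]
        x0[_IX["ERK"]] = self.totals["ERK"]
        return x0

    def snapshot(self) -> dict:
        """JSON-serializable dump of the assembled model for provenance:
        species, initial conditions, reactions, and parameter values."""
        x0 = self.resting_state()
        return {
            "construct": {
                "generation": self.construct.generation,
                "mech_grb2": self.construct.mech_grb2,
                "mech_gads": self.construct.mech_gads,
                "mech_lck_boost": self.construct.mech_lck_boost,
            },
            "species": list(SPECIES),
            "initial_state": {sp: float(x0[_IX[sp]]) for sp in SPECIES},
            "totals": dict(self.totals),
            "parameters": {n: float(self.theta[_PIX[n]]) for n in PARAM_NAMES},
            "reactions": [
                {"name": name, "stoichiometry": dict(stoich)}
                for name, stoich in _REACTIONS
            ],
            "conserved_moieties": {k: list(v) for k, v in CONSERVED_MOIETIES.items()},
        }

    def moiety_totals(self, x: np.ndarray) -> dict[str, np.ndarray]:
        return {
            name: sum(x[_IX[sp]] for sp in members)
            for name, members in CONSERVED_MOIETIES.items()
        }


def pack_theta(params: KineticParameterSet) -> np.ndarray:
    """Pack registry values into the rate-law parameter vector."""
    missing = [name for name in PARAM_NAMES if name not in params]
    if missing:
        raise ModelAssemblyError(
            f"rate laws reference parameters absent from the registry: {missing}"
        )
    return np.array([params[name] for name in PARAM_NAMES])


def assemble_model(
    construct: CARConstruct,
    params: KineticParameterSet,
    totals: dict[str, float] | None = None,
) -> ReactionNetwork:
    """Assemble the reaction network for a construct and parameter registry."""
    return ReactionNetwork(
        construct=construct,
        theta=pack_theta(params),
        totals=dict(DEFAULT_TOTALS if totals is None else totals),
    )
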