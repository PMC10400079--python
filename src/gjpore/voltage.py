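"""Constant-field voltage setup and protein net-charge accounting.

A transjunctional voltage V applied across a periodic box of length L_z
is modelled as a uniform axial electric field E_z = V / L_z.  The net
charge of the modelled protein (at neutral-pH protonation: Lys/Arg +1,
Asp/Glu -1, His neutral) determines the counterion imbalance needed to
neutralize the simulation box.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["FieldSetup", "compute_constant_field", "compute_net_charge", "ChargeReport"]

_POSITIVE = {"K", "R"}
_NEGATIVE = {"D", "E"}
_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class FieldSetup:
    """Applied voltage (mV), box length along the pore axis (A) and the
    resulting constant field (mV/A)."""

    V_applied: float
    L_z: float
    E_z: float


def compute_constant_field(V_applied: float, L_z: float) -> FieldSetup:
    """E_z = V_applied / L_z, sign preserved.

    Parameters
    ----------
    V_applied : float
        Transjunctional voltage in mV (signed).
    L_z : float
        Simulation box length along the diffusion axis, in A.
    """
    if L_z <= 0:
        raise ValueError(f"box length must be positive, got {L_z}")
    return FieldSetup(V_applied=V_applied, L_z=L_z, E_z=V_applied / L_z)


@dataclass
class ChargeReport:
    per_chain: list[int]
    termini: list[tuple[str, str]]
    total: int

    def to_dict(self) -> dict:
        return {
            "per_chain": self.per_chain,
            "termini": [list(t) for t in self.termini],
            "total": self.total,
        }


def compute_net_charge(
    sequence_per_chain: list[str],
    termini: str | list[tuple[str, str]] = "charged",
    pH_model: str = "neutral_default",
) -> ChargeReport:
    """Integer net charge (e) of a protein at neutral-pH protonation.

    Per chain: +1 for each Lys/Arg, -1 for each Asp/Glu, His neutral;
    +1 for a charged N-terminus and -1 for a charged C-terminus.
    ``termini`` is either a single state applied to every terminus or a
    per-chain list of (N-terminus, C-terminus) states, each "charged" or
    "neutral".  Chain-break termini introduced by unmodelled loops are
    treated like ordinary termini by the caller (one sequence fragment
    per modelled segment).
    """
    if pH_model != "neutral_default":
        raise ValueError(f"unknown pH model {pH_model!r}")
    if isinstance(termini, str):
        termini = [(termini, termini)] * len(sequence_per_chain)
    if len(termini) != len(sequence_per_chain):
        raise ValueError("termini list length must match number of chains")
    per_chain = []
    for seq, (nt, ct) in zip(sequence_per_chain, termini):
        q = 0
        for pos, aa in enumerate(seq.upper(), start=1):
            if aa not in _STANDARD:
                raise ValueError(f"nonstandard amino-acid letter {aa!r} at position {pos}")
            if aa in _POSITIVE:
                q += 1
            elif aa in _NEGATIVE:
                q -= 1
        for state, delta in ((nt, +1), (ct, -1)):
            if state not in {"charged", "neutral"}:
                raise ValueError(f"terminus state must be charged|neutral, got {state!r}")
            if state == "charged":
                q += delta
        per_chain.append(q)
    return ChargeReport(per_chain=per_chain, termini=list(termini), total=sum(per_chain))


def modeled_fragments_fasta() -> Path:
    """Path to the bundled FASTA with the modelled Cx43 sequence
    fragments (residues 2-105 and 151-235 of UniProt P17302)."""
    return Path(__file__).parent / "data" / "cx43_modeled_fragments.fasta"


def read_fasta_sequences(path: str | Path) -> list[str]:
    """Plain sequences (order preserved) from a FASTA file."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
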