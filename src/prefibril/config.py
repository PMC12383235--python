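"""Run configuration: the fixed physical constants and analysis defaults.

Every CLI run resolves a :class:`RunConfig` and embeds it (with the
package version and a config hash) in its output JSON, so results are
reproducible from the artifact alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    threshold_fraction: float = 0.15     # profile width convention
    window_ms: float = 2500.0            # conductance analysis window
    rho_ohm_cm: float = 80.0             # solution resistivity
    channel_length_nm: float = 5.4       # annular channel length
    strand_rise_nm: float = 0.48         # cross-beta rise per monomer
    density_conversion: float = 825.0    # Da per cubic angstrom

    def as_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {"config": self.as_dict(), "config_hash": self.hash(),
                "package_version": __version__}
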