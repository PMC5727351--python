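"""Packaged behavioral-assay scenarios.

``make_fixtures`` writes one experiment XML per validation scenario: the
angular/longitudinal touch sweeps are parameter scans done in code, but the
runnable assays (quadrants, drop, thermal gradient, proprioception,
collision, plate-tap, shock train, light pulses) are shipped as files.
Durations and timesteps are scaled to a few hundred steps per run; the
physical parameters (concentrations, temperatures, shock train, beam) match
the documented assay conditions.
"""

from __future__ import annotations

import os

FIXTURES: dict[str, str] = {
    "tap.xml": """\
<experiment dt="0.01" tEnd="3.0" seed="0">
  <plate diameter="50"/>
  <worm x="0" y="0" heading="0" amplitude="0.1" frequency="0.3" speed="0.1"/>
  <events>
    <plateTap amplitude="100" onset="1.0" duration="0.5"/>
  </events>
</experiment>
""",
    "shock.xml": """\
<experiment dt="0.005" tEnd="3.0" seed="0">
  <plate diameter="50"/>
  <worm x="0" y="0" heading="0"/>
  <events>
    <electricShock amplitude="10" frequency="10" pulseDuration="0.02"
                   onset="0.5" trainDuration="2.0"/>
  </events>
</experiment>
""",
    "light.xml": """\
<experiment dt="0.005" tEnd="4.0" seed="0">
  <plate diameter="50"/>
  <worm x="0" y="0" heading="0" speed="0"/>
  <events>
    <lightPulse u="0.05" radius="0.2" intensity="1" onset="0.3" duration="0.19"/>
    <lightPulse u="0.20" radius="0.2" intensity="2" onset="0.9" duration="0.19"/>
    <lightPulse u="0.40" radius="0.2" intensity="3" onset="1.5" duration="0.19"/>
    <lightPulse u="0.60" radius="0.2" intensity="4" onset="2.1" duration="0.19"/>
    <lightPulse u="0.80" radius="0.2" intensity="5" onset="2.7" duration="0.19"/>
    <lightPulse u="0.95" radius="0.2" intensity="6" onset="3.3" duration="0.19"/>
  </events>
</experiment>
""",
    "quadrants.xml": """\
<experiment dt="0.02" tEnd="16.0" seed="0">
  <plate diameter="50"/>
  <worm x="-2.5" y="-3.0" heading="0" amplitude="0.1" wavelength="0.65"
        frequency="0.4" speed="0.4"/>
  <events>
    <quadrants q1="butanone:30" q2="quinine:10" q3="biotin:44" q4="ethanol:60"
               barrier="NaCl:20" barrierWidth="2"/>
  </events>
</experiment>
""",
    "drop.xml": """\
<experiment dt="0.02" tEnd="16.0" seed="0">
  <plate diameter="50"/>
  <worm x="0" y="0" heading="0" amplitude="0.1" wavelength="0.65"
        frequency="0.5" speed="0.25"/>
  <events>
    <chemDrop substance="butanone" amount="50" x="2.2" y="0.35" onset="0"
              D="1e-4" radius="0.25"/>
  </events>
</experiment>
""",
    "thermal_gradient.xml": """\
<experiment dt="0.02" tEnd="10.0" seed="0">
  <plate diameter="50"/>
  <worm x="-10" y="0" heading="0" amplitude="0.1" wavelength="0.65"
        frequency="0.4" speed="0.3"/>
  <events>
    <thermalGradient left="25" right="20"/>
  </events>
</experiment>
""",
    "global_temp.xml": """\
<experiment dt="0.02" tEnd="8.0" seed="0">
  <plate diameter="50"/>
  <worm x="0" y="0" heading="0"/>
  <events>
    <globalTemp base="20" start="15" end="25" onset="2.0" duration="4.0"/>
  </events>
</experiment>
""",
    "proprioception.xml": """\
<experiment dt="0.02" tEnd="8.0" seed="0">
  <plate diameter="50"/>
  <worm x="0" y="0" heading="0" amplitude="0.1" wavelength="0.65"
        frequency="0.5" speed="0"/>
  <events>
    <proprioception curvature="on" stretch="on"/>
  </events>
</experiment>
""",
    "collision.xml": """\
<experiment dt="0.02" tEnd="4.0" seed="0">
  <plate diameter="50"/>
  <worm x="0" y="0" heading="0" amplitude="0.05" wavelength="0.65"
        frequency="0.4" speed="0.02"/>
  <obstacles>
    <disc x="-0.1" y="0.22" radius="0.2"/>
  </obstacles>
</experiment>
""",
}


def make_fixtures(directory: str) -> list[str]:
    """Write every packaged scenario file into ``directory``; returns paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, text in FIXTURES.items():
        path = os.path.join(directory, name)
        with open(path, "w") as fh:
            fh.write(text)
        paths.append(path)
    return paths
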