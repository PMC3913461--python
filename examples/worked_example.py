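"""Build and combine the two domain timelines for a short episode excerpt.

A rescuer-annotated excerpt (compressions at 805.2-887.2 and 938.8-1062.0 s,
a shock at 903.3-908.3 s; rhythm VF from 793.6 s, briefly PEA at
908.3-944.0 s) is turned into the therapy and response state sequences and
joined into the combined episode representation.
"""

import roreview as rv
from roreview.core import Event

therapy = rv.build_therapy_sequence(
    [
        Event("c1", 805.2), Event("c2", 887.2),
        Event("d1", 903.3), Event("d2", 908.3),
        Event("c1", 938.8), Event("c2", 1062.0),
    ],
    span_start=740.8,
    span_end=1062.0,
)
response = rv.build_response_sequence(
    [Event("vf", 793.6), Event("pe", 908.3), Event("vf", 944.0)],
    span_end=1062.0,
)

episode = rv.Episode(
    therapy=therapy,
    response=response,
    shocks=(rv.ShockRecord(903.3, energy_j=200.0, impedance_ohm=85.0),),
)
print(rv.write_rore(episode))
# The final block is the combined representation: 7 states, starting where
# the rhythm annotation begins (793.6 s), each label = therapy + rhythm
# (e.g. DVF = defibrillation during ventricular fibrillation).
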