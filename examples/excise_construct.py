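"""Integrate and excise a piggyBac selection cassette, footprint-free.

piggyBac integrates at a TTAA tetranucleotide and duplicates it; the
excision-only transposase removes the cassette together with one duplicate,
restoring the original locus exactly.
"""

from clonescreen import DonorConstruct, excise_cassette, integrate_cassette
from clonescreen.synthetic_sequences import make_cassette, make_template

locus = make_template(seed=3)
construct = DonorConstruct(cassette=make_cassette(seed=3, length=300))

knockin = integrate_cassette(locus, construct)
print(f"locus {len(locus)} bp -> knock-in {len(knockin)} bp (cassette + duplicated TTAA)")

result = excise_cassette(knockin, construct)
print(f"after excision: {len(result.sequence)} bp, restored exactly: "
      f"{result.sequence.bases == locus.bases}")

again = excise_cassette(result.sequence, construct)
print(f"second excision changes nothing (idempotent): {again.sequence.bases == result.sequence.bases}")

span = construct.left_arm_length + construct.right_arm_length
print(f"donor homology span: {construct.left_arm_length} + {construct.right_arm_length} = {span} bp")
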