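"""Karlin-Altschul constants fitted by scripts/fit_evalue_constants.py.

Null model: uniform random pairs of length 128 x 128; 20000 DNA and 8000 protein trials, RNG seed 20220914.
"""

DNA_LAMBDA = 0.6171027283899975
DNA_K = 0.2180331164912702
PROT_LAMBDA = 0.24688458075178596
PROT_K = 0.044217824792426134
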