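# Illustrative Ser/Thr kinase recognition patterns (synthetic example file).
# One motif per line; the phospho-acceptor is the lowercase s/t, X is a
# wildcard, uppercase letters are fixed residues.  These are common textbook
# motif shapes assembled for demonstration and testing of the pattern-tally
# tools -- they are NOT a curated catalogue of kinase specificities.
sP
sPXR
RXXs
RRXs
KKXs
sXXE
sXXXM
sM
sXMX
QXsXXM
sXXXMF
RXXsM
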