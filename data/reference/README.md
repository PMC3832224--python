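Place downloaded GenBank flat files of the deposited replicons here to
enable the deposited-genome checks in the test suite:

    CP005963.gb   ("Spiribacter salinus" M19-40)
    CP005990.gb   ("Spiribacter" sp. UAH-SP71)

Extensions .gb, .gbk, .gbff and .genbank are recognized.  Without these
files the corresponding tests skip; nothing else depends on them.
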