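>sSgII_master_synthetic synthetic scaffold; segments 178-238 and 367-375 are the true proteoform modules
MTLRFQIYNSDTALTWWQRRTRFCGSQFGKMSFAFTVRRNLHQRHCWNAQKTWIMQSSHA
GGFWGDEYRDCGKMIHGFLQTVLYYFYAEWQFLVSVTEWCFCKTIESKKQKFMFSDQDDC
AIVMDVQDNLSFQLQIHLFMGWAAQNGHVWGLIGNMVWGDFIKHCDICRDFSFEESVFKR
TNEMVEEQYTPQNLATLESVFQELGKLTGPNNQKHERADEEQKLYTDDEDDIYKANNIAI
QAPEPYWMNLIPKAKICYQMNDQASYHLLREAKSGLGVSRTNRCPPGWVAWKSFAMWPNM
TADACQWHYWYNFNDFDYGMMAGHFFWVAYYCYHVHTSPRDNGYQFSKDIEHLRCSAQQP
QVFQDWMLKTGEKPVLGTWLPYAIMTGLIITVFYYIGCLM
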