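>H2AZ1_HUMAN histone H2A.Z.1, Homo sapiens; curated reference sequence assembled offline from the literature (one residue near the alphaN/L region may differ from the database entry), numbering includes the initiator Met
MAGGKAGKDSGKAKTKAVSRSQRAGLQFPVGRIHRHLKSRTTSHGRVGATAAVYSAALQY
LTAEVLELAGNASKDLKVKRITPRHLQLAIRGDEELDSLIKATIAGGGVIPHIHKSLIGK
KGQQKTV
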