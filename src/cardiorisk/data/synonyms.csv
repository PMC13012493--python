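alias,canonical
hidroxicloroquina,hydroxychloroquine
cloroquina,chloroquine
acetaminophen,paracetamol
haldol,haloperidol
lasix,furosemide
azitromicina,azithromycin
midazolan,midazolam
metadona,methadone
tramal,tramadol
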