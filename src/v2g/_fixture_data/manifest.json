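{
 "printed_aggregates.json": "8451e756b2700318ab29513991f34ecdadad1deeaa6307749f6213a27f3ea08e",
 "table1.csv": "5c5a3e4ff5189dd15aef251f292011cadd610c593f33cbf2efefe96545947177",
 "table2.csv": "c25bf732064162a839fbffa80fe604c58c0756f264de56eaddf2a8bda0e1030f",
 "table3.csv": "9e1dce864d4da45344c97cfd4802e83b698207afc41dbb6c222a20a400d7de9c",
 "table4.csv": "8ac85d82a42239b88b6e5ac3f911882973e9f7e50ce6f04cdc7b6b3d3c182251",
 "table6.csv": "adbc528119767b52a4528760e78b1524f75446a72fd68ec8afa5947a39851f92"
}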