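[
 {
  "short_form": "BaP",
  "name": "benzo[a]pyrene",
  "cas_number": "50-32-8",
  "formula": "C20H12",
  "iarc_class": "1",
  "published_pefs": [
   [
    "CCME 2010",
    1.0
   ]
  ]
 },
 {
  "short_form": "BaA",
  "name": "benz[a]anthracene",
  "cas_number": "56-55-3",
  "formula": "C18H12",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "CCME 2010",
    0.1
   ]
  ]
 },
 {
  "short_form": "BbF",
  "name": "benzo[b]fluoranthene",
  "cas_number": "205-99-2",
  "formula": "C20H12",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "CCME 2010",
    0.1
   ]
  ]
 },
 {
  "short_form": "BjF",
  "name": "benzo[j]fluoranthene",
  "cas_number": "205-82-3",
  "formula": "C20H12",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "WHO/IPCS 1998",
    0.1
   ]
  ]
 },
 {
  "short_form": "BkF",
  "name": "benzo[k]fluoranthene",
  "cas_number": "207-08-9",
  "formula": "C20H12",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "CCME 2010",
    0.1
   ]
  ]
 },
 {
  "short_form": "BghiP",
  "name": "benzo[g,h,i]perylene",
  "cas_number": "191-24-2",
  "formula": "C22H12",
  "iarc_class": "3",
  "published_pefs": [
   [
    "CCME 2010",
    0.01
   ]
  ]
 },
 {
  "short_form": "CH",
  "name": "chrysene",
  "cas_number": "218-01-9",
  "formula": "C18H12",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "CCME 2010",
    0.01
   ]
  ]
 },
 {
  "short_form": "DBahA",
  "name": "dibenz[a,h]anthracene",
  "cas_number": "53-70-3",
  "formula": "C22H14",
  "iarc_class": "2A",
  "published_pefs": [
   [
    "CCME 2010",
    1.0
   ]
  ]
 },
 {
  "short_form": "IP",
  "name": "indeno[1,2,3-cd]pyrene",
  "cas_number": "193-39-5",
  "formula": "C22H12",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "CCME 2010",
    0.1
   ]
  ]
 },
 {
  "short_form": "BcFE",
  "name": "benzo[c]fluorene",
  "cas_number": "205-12-9",
  "formula": "C17H12",
  "iarc_class": "3",
  "published_pefs": [
   [
    "published",
    20.0
   ]
  ]
 },
 {
  "short_form": "BcPh",
  "name": "benzo[c]phenanthrene",
  "cas_number": "195-19-7",
  "formula": "C18H12",
  "iarc_class": "2B",
  "published_pefs": []
 },
 {
  "short_form": "CPP",
  "name": "cyclopenta[c,d]pyrene",
  "cas_number": "27208-37-3",
  "formula": "C18H10",
  "iarc_class": "2A",
  "published_pefs": [
   [
    "OEHHA 2019",
    0.1
   ]
  ]
 },
 {
  "short_form": "DBacA",
  "name": "dibenz[a,c]anthracene",
  "cas_number": "215-58-7",
  "formula": "C22H14",
  "iarc_class": "3",
  "published_pefs": [
   [
    "published",
    4.0
   ]
  ]
 },
 {
  "short_form": "DBaeF",
  "name": "dibenzo[a,e]fluoranthene",
  "cas_number": "5385-75-1",
  "formula": "C24H14",
  "iarc_class": "3",
  "published_pefs": [
   [
    "published",
    0.9
   ]
  ]
 },
 {
  "short_form": "DBaeP",
  "name": "dibenzo[a,e]pyrene",
  "cas_number": "192-65-4",
  "formula": "C24H14",
  "iarc_class": "3",
  "published_pefs": [
   [
    "EFSA 2008",
    1.0
   ]
  ]
 },
 {
  "short_form": "DBahP",
  "name": "dibenzo[a,h]pyrene",
  "cas_number": "189-64-0",
  "formula": "C24H14",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "EFSA 2008",
    10.0
   ]
  ]
 },
 {
  "short_form": "DBaiP",
  "name": "dibenzo[a,i]pyrene",
  "cas_number": "189-55-9",
  "formula": "C24H14",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "EFSA 2008",
    10.0
   ]
  ]
 },
 {
  "short_form": "DBalP",
  "name": "dibenzo[a,l]pyrene",
  "cas_number": "191-30-0",
  "formula": "C24H14",
  "iarc_class": "2A",
  "published_pefs": [
   [
    "OEHHA 2019",
    100.0
   ]
  ]
 },
 {
  "short_form": "5-MeC",
  "name": "5-methylchrysene",
  "cas_number": "3697-24-3",
  "formula": "C19H14",
  "iarc_class": "2B",
  "published_pefs": [
   [
    "OEHHA 2019",
    1.0
   ]
  ]
 }
]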