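>NUL0000.p1
MAPFQYARRKQMVSAFSAVSELSKAGDECSVVKAAYLFYGPERFCPLLVSARSARLSSPPPPKPAHGITHVKGLLIGRPYSIRPEPSATQL
>NUL0001.p1
MRSVTHSTGMNPACFPRPTHTAAFESVQFPPELTYIRGRVSPTTSSSGTRVGLHQPGQIAKVRASHGLRIGRTDDRTVRASNLGLRSLI
>NUL0001.p2
MRTITCYREVVFRQSRSSARPDHRLLLMQICPLREVCATRELSVQLVATTRISRITMFRLPWLEPLLLILRVDGLLFYQSAQLGATGSPMLSHTEAPTYGLVF
>NUL0002.p1
MIATLGCLSGVPGLVFGVCIILQVLPFLHVHRITCWRDVSTFIGDIQALLKAHIPSLRNPCLKWSSGLSRVRIWYDTRRLEKIDYYISSLSRYVKYPTTPSTCSHL
>NUL0003.p1
MNARAQSTQVCHYGVSSVKSRLLAMIRYKIDKEPTALRRPKSANNWESTLEAKTKFLLPCRGWRPLLLYSEMPVVTCSLQSLQPDIKLEPGHVYGCIRSNHRGSVYLEKKLVLNKDRGHHRRVLRSKNSYSYAELYPAD
>NUL0004.p1
MLLVRFWRSQKDRKPNRQPPVRRFVTPFWDVLIFCWTHVHRLGTMRCYRCSAHHSTTLSLEGTCDRCSILTRTPAAHRMLQNTRYPPYGMQSYYSQVVMRPMAKQFSHEFLLTHPIHSHRNELVREDYRVELCADSSKVQYNETVP
>NUL0004.p2
MDISPSEGHAGNCRRGSIKYRHIDLTKTSSLEGAGASVFPNRGCFAQGTSRFVNSTEGISPRIHCAL
>NUL0005.p1
MYKSTPPLSFRPSQRVTPREATNPQFHSELCYKVGVRGTEHSFALRAQQSFYTSGMEEARLPIHESTLKGDPRLLGRHSWGSKTLKYAKYRHRGSRCDASTGKHRSAEHGRYYDRSK
>POS0000.p1
MRGVKTKKFGARGPPPERLTGRSPKGTLPVNGGPASELANNDQPIPPPFFHPPPRGTPKKTVLYCPENVNVDPAQPPTIFQLDPILGLPIGARVFGHGKGSRNAQCSNLARAGDDRGGATRLLRFGFRMPHRPPFPNSSVPNTARG
>POS0000.p2
MRCILERLCTNRPARPKPISSDTPKGLPQLVPDFLSSRVIGDLKGGFCDYERNLPHEPCNPIPPPPGKLRPHMPRGLKNLVVVILLVAFALFLAIVAFIFTLPGMPLRGLIAQGAPKSFYPGPAGTVILV
>POS0001.p1
MARTTPTFVHRPPTVKGKLSGQLGSAPASLSPSPRQAPLPAWVNWTNKVPAFQSVNFAMF
>POS0002.p1
MGLQPDRGGNWVKMPTPCAALLLVLAILVLAFAFLVALIPGNPARFGDRVEGGWCLMREGYGGNPISSFGGFHGSNTAALLYLTPGPRPLAEPKWLLPPPHPPNLGPVPLNGKVLGKATGEKFRQGPGRNDPKPLQV
>POS0003.p1
MIQGGAVVLLAIAVLFLAAFFLFLVVGPLAGAPAPIRNHTQIQSRFLRTDSSAGFSGQEYHASEPVPPTLGPRPFLIRDNWQSKLGFASPNGPGRHVDFPQASLKEGNRSELGPLLALLSPRLAPRGPAQGVLGLGGPPGFLSPNHNATPPFKLSRRVVCSNGCRL
>POS0003.p2
MAFRTDGVGDPSVNRALFRLAPEHHGRASLPGPFGGVSVYPLRPNGSTRAVFLLVVALVVVLALFFIVFVGFGTLTLVPGAPPKAHFCRKPSTQNSMRPHVDAIELVP
>POS0004.p1
MFSPPLAPFPDPAFLAFFVVLVVALAFLLIAILPSPQGADPGYTRGSWPPGPGQIRSYLPAEPKKNAGFIGASGVLPCSWKGPNPSWWRAGQGQEGLGRRYGRKPAR
>POS0004.p2
MDGLPHPLSHPVEKSPVCLPNTNTFFATGVPPDPPDNLETLQSFRGEITPAQDKKWALNRVPWGDYLTLAEPALVGESRGEGGFCSAHGPAPGPPVFLLLLIFLLAVFIAAFFLFAL
>POS0005.p1
MQAWNGSPVKSSKGAPPIAQRRPQGAGGGETRLRPASPQTLKIVFAALAVVVVLFFFAAAVAVEFFPTFNPGW
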