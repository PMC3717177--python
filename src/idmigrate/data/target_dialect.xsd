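<?xml version="1.0" encoding="UTF-8"?>
<!-- Target (project/experiment) identification dialect, version 1.0.
     A minimal, versioned stand-in for an experiment-centric repository
     submission: a project holds experiments; each experiment holds the
     carried-over free-text metadata, taxon labels and MGF references, and
     nested identifications - protein items (one accession as reported by
     one search engine) containing the peptide items that support them. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="modOrigin">
    <xs:restriction base="xs:string">
      <xs:enumeration value="reported"/>
      <xs:enumeration value="fixed_annotation"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="metadataType">
    <xs:sequence>
      <xs:element name="Field" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:simpleContent>
            <xs:extension base="xs:string">
              <xs:attribute name="key" type="xs:string" use="required"/>
            </xs:extension>
          </xs:simpleContent>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="modificationType">
    <xs:attribute name="position" type="xs:nonNegativeInteger" use="required"/>
    <xs:attribute name="accession" type="xs:string" use="required"/>
    <xs:attribute name="monoDelta" type="xs:double" use="required"/>
    <xs:attribute name="origin" type="modOrigin" use="required"/>
  </xs:complexType>

  <xs:complexType name="scoreType">
    <xs:attribute name="engine" type="xs:string" use="required"/>
    <xs:attribute name="value" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="peptideItemType">
    <xs:sequence>
      <xs:element name="Modification" type="modificationType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="Score" type="scoreType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:string" use="required"/>
    <xs:attribute name="sequence" type="xs:string" use="required"/>
    <xs:attribute name="spectrumRef" type="xs:string" use="required"/>
    <xs:attribute name="charge" type="xs:nonNegativeInteger" use="required"/>
  </xs:complexType>

  <xs:element name="TargetProject">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="Experiment" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Metadata" type="metadataType" minOccurs="0"/>
              <xs:element name="Taxa" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Taxon" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="Engines" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Engine" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="SpectrumFiles" minOccurs="0">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="SpectrumFile" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="ProteinItem" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="PeptideItem" type="peptideItemType" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="accession" type="xs:string" use="required"/>
                  <xs:attribute name="searchEngine" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="sourceSample" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="dialectVersion" type="xs:string" use="required"/>
      <xs:attribute name="sourceStudy" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
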